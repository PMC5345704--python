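"""Grid construction, equilibrium spectra, and solver behavior.

The deeper dynamical checks (stationarity, bottleneck limits, oracle
agreement) live in the acceptance suite; these tests cover construction
properties, mass-balance bookkeeping, error paths, and counterfactuals.
"""

import numpy as np
import pytest
from scipy.integrate import quad

import sfsdyn as sd
from sfsdyn.diffusion import ParameterError, _bernoulli, equilibrium_spectrum


class TestMakeGrid:
    def test_uniform_when_refinement_one(self):
        g = sd.make_grid(100, 1.0)
        assert np.allclose(np.diff(g.points), g.points[0])
        assert g.n_points == 100

    def test_refined_grid_monotone_spacing(self):
        g = sd.make_grid(2000, 3.0)
        dx = np.diff(g.points)
        assert np.all(np.diff(dx) > 0)  # spacing grows away from zero
        assert g.points[0] < 1.0 / 2000**2

    def test_quadrature_closes_neutral_integral(self, neutral_eq):
        # int x(1-x) * (theta/x) dx = theta/2 exactly for linear g
        val = sd.summaries.integrate_against(
            neutral_eq, lambda x: x * (1.0 - x), dphi0=1.0)
        assert val == pytest.approx(0.5, rel=1e-4)

    def test_too_small_rejected(self):
        with pytest.raises(ParameterError):
            sd.make_grid(10)

    def test_face_geometry_consistent(self, grid):
        assert grid.faces[0] == 0.0 and grid.faces[-1] == 1.0
        assert grid.widths.sum() == pytest.approx(1.0)


class TestEquilibriumSpectrum:
    def test_neutral_midpoint_value(self, grid):
        eq = equilibrium_spectrum(sd.ScenarioParams(S=0.0, theta=1.0), grid)
        mid = np.argmin(np.abs(grid.points - 0.5))
        assert eq.values[mid] == pytest.approx(1.0 / grid.points[mid], rel=1e-9)

    @pytest.mark.parametrize("S", [0.0, 0.5, 10.0, 150.0, -3.0])
    def test_boundary_datum(self, grid, S):
        eq = equilibrium_spectrum(sd.ScenarioParams(S=S, theta=2.5), grid)
        x = grid.points[:3]
        g = x * (1 - x) * eq.values[:3]
        # x(1-x) f -> theta as x -> 0
        assert g[0] == pytest.approx(2.5, rel=1e-4)

    def test_heterozygosity_matches_adaptive_quadrature(self, grid):
        S, theta = 10.0, 1.0
        eq = equilibrium_spectrum(sd.ScenarioParams(S=S, theta=theta), grid)
        def integrand(x):
            kern = (np.exp(-2 * S * x) - np.exp(-2 * S)) / (1 - np.exp(-2 * S))
            return 2.0 * theta * kern
        oracle, _ = quad(integrand, 0.0, 1.0)
        assert sd.heterozygosity(eq) == pytest.approx(oracle, rel=1e-3)
        assert sd.equilibrium_heterozygosity(S, theta) == pytest.approx(
            oracle, rel=1e-9)

    def test_large_S_stable(self, grid):
        eq = equilibrium_spectrum(sd.ScenarioParams(S=500.0, theta=1.0), grid)
        assert np.all(np.isfinite(eq.values)) and np.all(eq.values >= 0)


class TestBernoulli:
    def test_limits(self):
        z = np.array([-800.0, -1.0, -1e-9, 0.0, 1e-9, 1.0, 800.0])
        b = _bernoulli(z)
        assert b[3] == pytest.approx(1.0)
        assert b[-1] == pytest.approx(0.0, abs=1e-12)
        assert b[0] == pytest.approx(800.0)  # B(z) -> -z as z -> -inf
        # identity B(-z) - B(z) = z
        diff = _bernoulli(np.array([-2.5]))[0] - _bernoulli(np.array([2.5]))[0]
        assert diff == pytest.approx(2.5, abs=1e-12)


class TestSolve:
    def test_mass_balance_over_solve(self, grid, solver_config):
        """Cell mass change equals injected - lost - fixed exactly."""
        params = sd.ScenarioParams(S=5.0, theta=1.0)
        init = equilibrium_spectrum(params, grid)
        model = sd.preset_bottleneck(0.3, 400.0, two_N0=2000.0)
        out = sd.solve(init, model, solver_config, t_start_gen=400.0)[-1]
        delta = out.segregating_mass() - init.segregating_mass()
        balance = out.injected_mass - out.lost_mass - out.fixed_mass
        scale = max(abs(out.injected_mass), abs(out.fixed_mass), 1.0)
        assert delta == pytest.approx(balance, abs=1e-8 * scale)

    def test_positivity_through_growth(self, grid, solver_config, models):
        params = sd.ScenarioParams.from_rates(s=1e-3, two_N0=29_240.0)
        init = equilibrium_spectrum(params, grid, rho=0.5)
        out = sd.solve(init, models["ooa"], solver_config)[-1]
        assert np.all(out.values >= 0)
        assert out.fixed_mass >= 0 and out.lost_mass >= 0

    def test_absorbed_masses_nondecreasing(self, grid, solver_config):
        params = sd.ScenarioParams(S=20.0, theta=1.0)
        init = equilibrium_spectrum(params, grid)
        model = sd.preset_bottleneck(0.13, 600.0, two_N0=2000.0)
        cfg = sd.SolverConfig(dt=1e-3, n_grid=800,
                              snapshot_gens=tuple(np.linspace(600, 0, 13)))
        snaps = sd.solve(init, model, cfg, t_start_gen=600.0)
        fixed = [s.fixed_mass for s in snaps]
        lost = [s.lost_mass for s in snaps]
        assert np.all(np.diff(fixed) >= -1e-14)
        assert np.all(np.diff(lost) >= -1e-14)

    def test_window_validation(self, grid, solver_config, models):
        init = equilibrium_spectrum(sd.ScenarioParams(S=0.0, theta=1.0), grid)
        with pytest.raises(ParameterError):
            sd.solve(init, models["ooa"], solver_config,
                     t_start_gen=100.0, t_end_gen=200.0)
        with pytest.raises(ParameterError):
            sd.solve(init, models["ooa"], solver_config, t_start_gen=1e6)

    def test_snapshot_times_hit(self, grid, solver_config):
        model = sd.preset_constant(2000.0, 1000.0)
        init = equilibrium_spectrum(sd.ScenarioParams(S=0.0, theta=1.0), grid)
        cfg = sd.SolverConfig(dt=1e-3, n_grid=800,
                              snapshot_gens=(800.0, 500.0, 0.0))
        snaps = sd.solve(init, model, cfg)
        got = [s.time_gen for s in snaps]
        assert len(got) == 3
        for want, have in zip([800.0, 500.0, 0.0], got):
            assert abs(want - have) <= 1e-3 * 2000.0 + 1e-9

    def test_self_convergence_on_ooa(self, models):
        """Halving dt and doubling the grid moves present-day summaries by
        well under the 0.2% contract."""
        ooa = models["ooa"]
        vals = {}
        for n_grid, dt in ((800, 2e-3), (1600, 1e-3)):
            cfg = sd.SolverConfig(dt=dt, n_grid=n_grid)
            g = cfg.make_grid()
            params = sd.ScenarioParams.from_rates(s=6.31e-4, two_N0=29_240.0)
            init = equilibrium_spectrum(params, g, rho=0.5)
            out = sd.solve(init, ooa, cfg)[-1]
            vals[n_grid] = np.array([
                sd.heterozygosity(out),
                sd.derived_burden(out),
                sd.prob_polymorphic(out, 20),
            ])
        rel = np.abs(vals[1600] / vals[800] - 1.0)
        assert np.all(rel < 2e-3)


class TestNoSelectionCounterfactual:
    def test_no_mutation_mass_decays(self, grid, solver_config):
        init = equilibrium_spectrum(sd.ScenarioParams(S=0.0, theta=1.0), grid)
        model = sd.preset_constant(2000.0, 1000.0)
        out = sd.no_selection_counterfactual(
            init, model, solver_config, keep_mutation=False)[-1]
        assert out.segregating_mass() < init.segregating_mass()
        assert out.injected_mass == 0.0

    def test_equals_solve_for_neutral_input(self, grid, solver_config):
        init = equilibrium_spectrum(sd.ScenarioParams(S=0.0, theta=1.0), grid)
        model = sd.preset_bottleneck(0.5, 300.0, two_N0=2000.0)
        a = sd.solve(init, model, solver_config, t_start_gen=300.0)[-1]
        b = sd.no_selection_counterfactual(
            init, model, solver_config, keep_mutation=True,
            t_start_gen=300.0)[-1]
        assert np.allclose(a.values, b.values)

    def test_neutral_burden_difference_is_zero(self, grid, solver_config,
                                               models):
        """Two populations sharing an ancestor accumulate identical burden
        without selection, whatever their size histories."""
        params = sd.ScenarioParams.from_rates(s=6.31e-4, two_N0=29_240.0)
        init = equilibrium_spectrum(params, grid, rho=0.5)
        pre = sd.solve(init, models["ooa"], solver_config,
                       t_end_gen=2000.0)[-1]
        finals = {
            pop: sd.no_selection_counterfactual(
                pre, models[pop], solver_config, keep_mutation=True,
                t_start_gen=2000.0)[-1]
            for pop in ("african", "ooa")
        }
        d = (sd.derived_burden(finals["african"])
             - sd.derived_burden(finals["ooa"]))
        base = sd.derived_burden(finals["african"])
        assert abs(d) < 1e-4 * base
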