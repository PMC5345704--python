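"""Sample-SFS projection, spectrum summaries, and PN/PT machinery."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import comb

import sfsdyn as sd
from sfsdyn.diffusion import ParameterError, equilibrium_spectrum
from sfsdyn.summaries import (
    RateParams,
    derived_burden,
    derived_hom,
    heterozygosity,
    per_mb_scaling,
    pn_pt,
    pnpt_selection_rate_population,
    pnpt_selection_rate_sample,
    prob_polymorphic,
    sample_sfs,
)


@pytest.fixture(scope="module")
def selected_eq(grid):
    return equilibrium_spectrum(sd.ScenarioParams(S=10.0, theta=1.0), grid)


class TestSampleSFS:
    def test_neutral_sfs_is_theta_over_k(self, neutral_eq):
        sfs = sample_sfs(neutral_eq, 12)
        k = np.arange(1, 12)
        assert np.allclose(sfs.expected_counts, 1.0 / k, rtol=2e-4)

    def test_q21_equals_heterozygosity(self, selected_eq):
        sfs = sample_sfs(selected_eq, 2)
        assert sfs.expected_counts[0] == pytest.approx(
            heterozygosity(selected_eq), rel=1e-12)

    def test_q75_matches_expanded_integrand(self, selected_eq):
        """E[q_{7,5}] written out as C(7,5) int (x^5 - 2x^6 + x^7) f dx."""
        sfs = sample_sfs(selected_eq, 7)
        expanded = sd.summaries.integrate_against(
            selected_eq,
            lambda x: comb(7, 5) * (x**5 - 2 * x**6 + x**7),
            dphi0=0.0,
        )
        assert sfs.expected_counts[4] == pytest.approx(expanded, rel=1e-10)

    def test_totals_match_prob_polymorphic(self, selected_eq, neutral_eq):
        for f in (selected_eq, neutral_eq):
            for n in (5, 20):
                sfs = sample_sfs(f, n)
                assert sfs.total_polymorphic() == pytest.approx(
                    prob_polymorphic(f, n), rel=1e-6)

    def test_small_n_rejected(self, neutral_eq):
        with pytest.raises(ParameterError):
            sample_sfs(neutral_eq, 1)

    def test_large_sample_finite(self, neutral_eq):
        sfs = sample_sfs(neutral_eq, 5000)
        assert np.all(np.isfinite(sfs.expected_counts))
        assert np.all(sfs.expected_counts >= 0)


class TestMomentSummaries:
    def test_neutral_heterozygosity_is_theta(self, neutral_eq):
        assert heterozygosity(neutral_eq) == pytest.approx(1.0, rel=1e-6)

    def test_zero_spectrum(self, grid):
        f = sd.FrequencySpectrum(
            grid=grid, values=np.zeros(grid.n_points),
            params=sd.ScenarioParams(S=0.0, theta=0.0), boundary_theta=0.0,
            fixed_mass=0.7)
        assert heterozygosity(f) == 0.0
        assert derived_hom(f) == pytest.approx(0.7)
        assert derived_burden(f) == pytest.approx(1.4)

    def test_burden_identity(self, selected_eq, neutral_eq):
        """2x = 2x(1-x) + 2x^2 pointwise, so burden = het + 2 hom."""
        for f in (selected_eq, neutral_eq):
            assert derived_burden(f) == pytest.approx(
                heterozygosity(f) + 2.0 * derived_hom(f), rel=1e-6)

    def test_selected_hom_matches_quadrature_oracle(self, selected_eq):
        S = 10.0
        def integrand(x):
            kern = (np.exp(-2 * S * x) - np.exp(-2 * S)) / (1 - np.exp(-2 * S))
            return x**2 * kern / (x * (1 - x))
        oracle, _ = quad(integrand, 0.0, 1.0)
        assert derived_hom(selected_eq) == pytest.approx(oracle, rel=1e-3)

    def test_neutral_burden_growth_rate(self, grid):
        """At neutral stationarity the burden grows at theta per coalescent
        unit: theta/2 from new fixations times two alleles per genome."""
        cfg = sd.SolverConfig(dt=1e-3, n_grid=800)
        init = equilibrium_spectrum(sd.ScenarioParams(S=0.0, theta=1.0), grid)
        model = sd.preset_constant(2000.0, 1000.0)
        out = sd.solve(init, model, cfg, t_start_gen=500.0)[-1]  # tau = 0.25
        rate = (derived_burden(out) - derived_burden(init)) / out.time
        assert rate == pytest.approx(1.0, rel=0.02)


class TestProbPolymorphic:
    def test_watterson(self, neutral_eq):
        for n in (2, 10, 40):
            expected = sum(1.0 / i for i in range(1, n))
            assert prob_polymorphic(neutral_eq, n) == pytest.approx(
                expected, rel=1e-3)

    def test_monotone_in_n(self, selected_eq, neutral_eq):
        for f in (selected_eq, neutral_eq):
            assert prob_polymorphic(f, 20) >= prob_polymorphic(f, 10)


class TestPnPt:
    def test_identical_spectra_two_to_one(self, grid):
        fS = equilibrium_spectrum(sd.ScenarioParams(S=0.0, theta=1.0), grid)
        fN = equilibrium_spectrum(sd.ScenarioParams(S=0.0, theta=2.0), grid)
        assert pn_pt(fN, fS, 10).ratio == pytest.approx(2.0 / 3.0, rel=1e-6)

    def test_strong_selection_drives_ratio_down(self, grid):
        fS = equilibrium_spectrum(sd.ScenarioParams(S=0.0, theta=1.0), grid)
        fN = equilibrium_spectrum(sd.ScenarioParams(S=400.0, theta=2.0), grid)
        assert pn_pt(fN, fS, 10).ratio < 0.2

    def test_equilibrium_ratio_decreases_with_S_and_size(self, grid):
        """Mirrors the equilibrium contrast between the pre- and
        post-bottleneck population sizes."""
        ratios = {}
        for two_N in (3801.0, 29_240.0):
            row = []
            for s in (1e-4, 1e-3, 1e-2):
                S = two_N * s
                fN = equilibrium_spectrum(
                    sd.ScenarioParams(S=S, theta=2.0), grid)
                fS = equilibrium_spectrum(
                    sd.ScenarioParams(S=0.0, theta=1.0), grid)
                row.append(pn_pt(fN, fS, 20).ratio)
            ratios[two_N] = np.array(row)
            assert np.all(np.diff(row) < 0)  # decreasing in s
        assert np.all(ratios[3801.0] > ratios[29_240.0])

    def test_ooa_trajectory_dips_then_rises(self, models):
        """PN/PT in a moderately large sample drops at the bottleneck and
        rises again during the later growth phase."""
        ooa = models["ooa"]
        snap = (2001.0, 1500.0, 920.0, 0.0)
        cfg = sd.SolverConfig(dt=1e-3, n_grid=800, snapshot_gens=snap)
        grid = cfg.make_grid()
        params = sd.ScenarioParams.from_rates(s=6.31e-4, two_N0=29_240.0)
        initN = equilibrium_spectrum(
            params.replace(theta=2 * params.theta), grid, rho=0.5)
        initS = equilibrium_spectrum(
            params.replace(S=0.0), grid, rho=0.5)
        fN = sd.solve(initN, ooa, cfg)
        fS = sd.solve(initS, ooa, cfg)
        traj = [pn_pt(a, b, 200).ratio for a, b in zip(fN, fS)]
        before_b, during, at_c, present = traj
        assert during < before_b          # bottleneck loss of rare variants
        assert present > min(during, at_c)  # recovery during growth


class TestSelectionRates:
    def test_population_rate_algebra(self):
        rp = RateParams(S=5.0, theta_N=2.0, k=10)
        base = pnpt_selection_rate_population(rp, PN=1.0, PS=3.0)
        assert base == pytest.approx(-5.0 * 2.0 * 3.0 / 16.0)
        # doubling PN with PS fixed weakens the rate
        weaker = pnpt_selection_rate_population(rp, PN=2.0, PS=3.0)
        assert abs(weaker) < abs(base)
        assert pnpt_selection_rate_population(
            RateParams(S=0.0, theta_N=1.0), 1.0, 1.0) == 0.0

    def test_sample_rate_zero_and_sign(self):
        assert pnpt_selection_rate_sample(
            RateParams(S=0.0, theta_N=1.0, k=5), 1.0, 1.0) == 0.0
        for S in (0.5, 5.0, 50.0):
            for k in (2, 10, 100):
                r = pnpt_selection_rate_sample(
                    RateParams(S=S, theta_N=1.0, k=k), 1.0, 1.0)
                assert r <= 0.0


class TestPerMbScaling:
    def test_linearity(self):
        v = per_mb_scaling(3.0, theta_solved=1.0, two_N0=1000.0, mu=1e-8)
        assert per_mb_scaling(6.0, 1.0, 1000.0, mu=1e-8) == pytest.approx(2 * v)
        assert per_mb_scaling(3.0, 2.0, 1000.0, mu=1e-8) == pytest.approx(v / 2)
        assert per_mb_scaling(3.0, 1.0, 1000.0, mu=0.0) == 0.0

    def test_units(self):
        # raw value 1 at theta=1 scaled to theta_Mb = 2*2N0*1e6*mu*frac
        got = per_mb_scaling(1.0, 1.0, two_N0=29_240.0, mu=1.2e-8,
                             nonsyn_fraction=2 / 3)
        assert got == pytest.approx(2 * 29_240.0 * 1e6 * 1.2e-8 * 2 / 3)
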