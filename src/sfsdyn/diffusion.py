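"""Forward-in-time diffusion of the population frequency spectrum.

The frequency spectrum f(x, t) (expected density of derived alleles at
population frequency x) evolves under genic selection and drift as

    df/dt = d/dx [ S x(1-x) f ] + (1/2) d2/dx2 [ x(1-x) f / rho(t) ],

with S = 2 N0 s the scaled selection coefficient (S > 0 deleterious),
rho(t) the population size relative to N0, and time in units of 2 N0
generations.  Mutational input enters through the low-frequency boundary

    lim_{x->0} x(1-x) f = theta * rho(t),      theta = 4 N0 l mu,

while x(1-x) f -> 0 at the high-frequency boundary.  Probability flux
absorbed at x = 1 is the expected number of fixations; flux leaving at
x = 0 beyond the mutational injection is the expected number of losses.

Numerics
--------
The equation is discretized in conservative finite-volume form on a
nonuniform vertex-centered grid refined toward x = 0.  Writing
g = x(1-x) f, the probability flux is J = -S g - g'/(2 rho); fluxes at cell
faces use exponential (Scharfetter-Gummel) fitting, which is exact for the
constant-flux exponential profiles that make up the equilibrium spectrum.
Consequences: the closed-form equilibrium is a fixed point of the discrete
scheme up to roundoff, the scheme is positivity-preserving under backward
Euler, and discrete mass balance (change in cell mass = net boundary flux)
holds exactly.  Time stepping is Crank-Nicolson with two backward-Euler
startup steps after every size discontinuity (Rannacher smoothing) to damp
the non-smooth transient; default step 1e-3 in units of 2 N0 generations.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .demography import DemographicModel

__all__ = [
    "Grid",
    "ScenarioParams",
    "FrequencySpectrum",
    "SolverConfig",
    "make_grid",
    "equilibrium_spectrum",
    "equilibrium_heterozygosity",
    "solve",
    "no_selection_counterfactual",
    "write_snapshots",
    "SolverInstabilityError",
    "ParameterError",
]

logger = logging.getLogger(__name__)


class SolverInstabilityError(RuntimeError):
    """Solver produced non-finite values or negative mass beyond tolerance."""


class ParameterError(ValueError):
    pass


# Negative values beyond -NEG_TOL * max(f) abort the solve; smaller
# excursions are clipped to zero.
NEG_TOL = 1e-12


@dataclass(frozen=True)
class Grid:
    """Strictly increasing interior points in (0, 1) plus derived geometry.

    ``faces`` are the finite-volume cell boundaries: 0, the midpoints
    between consecutive nodes, and 1.  ``widths`` are cell sizes and
    ``spacings`` the node-to-node distances entering the face fluxes.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.points, dtype=float)
        if x.ndim != 1 or x.size < 3:
            raise ParameterError("grid needs at least 3 interior points")
        if not (np.all(np.diff(x) > 0) and 0 < x[0] and x[-1] < 1):
            raise ParameterError("grid points must be strictly increasing in (0,1)")
        object.__setattr__(self, "points", x)

    @property
    def n_points(self) -> int:
        return self.points.size

    @property
    def faces(self) -> np.ndarray:
        x = self.points
        return np.concatenate(([0.0], 0.5 * (x[1:] + x[:-1]), [1.0]))

    @property
    def widths(self) -> np.ndarray:
        f = self.faces
        return f[1:] - f[:-1]

    @property
    def spacings(self) -> np.ndarray:
        """Node separations at each face: [x1 - 0, x2 - x1, ..., 1 - xM]."""
        x = self.points
        return np.concatenate(([x[0]], np.diff(x), [1.0 - x[-1]]))


def make_grid(n_points: int = 2000, refinement: float = 3.0) -> Grid:
    """Power-law graded grid x_i = (i / (M+1))**refinement.

    ``refinement`` = 1 gives uniform spacing; larger values concentrate
    points near x = 0 where strongly selected and growth-inflated spectra
    are peaked.  Spacing increases monotonically with x.
    """
    if n_points < 50:
        raise ParameterError("n_points must be at least 50")
    if refinement < 1.0:
        raise ParameterError("refinement must be >= 1")
    u = np.arange(1, n_points + 1, dtype=float) / (n_points + 1)
    return Grid(u**refinement)


@dataclass(frozen=True)
class ScenarioParams:
    """Selection and mutation parameters in diffusion units.

    ``S`` = 2 N0 s and ``theta`` = 4 N0 l mu are what the solver consumes;
    ``s``, ``mu``, ``l`` and ``two_N0`` are retained for bookkeeping and
    unit conversion when constructed via :meth:`from_rates`.
    """

    S: float
    theta: float
    s: float | None = None
    mu: float | None = None
    l: float | None = None
    two_N0: float | None = None

    def __post_init__(self) -> None:
        if not self.theta >= 0:
            raise ParameterError("theta must be nonnegative")
        if not np.isfinite(self.S):
            raise ParameterError("S must be finite")

    @classmethod
    def from_rates(
        cls, s: float, two_N0: float, mu: float = 1.2e-8, l: float = 1e6
    ) -> "ScenarioParams":
        """Build from per-generation rates: S = 2N0 s, theta = 4 N0 l mu."""
        return cls(
            S=two_N0 * s, theta=2.0 * two_N0 * l * mu,
            s=s, mu=mu, l=l, two_N0=two_N0,
        )

    def replace(self, **kw) -> "ScenarioParams":
        return dataclasses.replace(self, **kw)


@dataclass
class FrequencySpectrum:
    """Solver state: f at the grid nodes plus absorbed boundary mass.

    ``boundary_theta`` is the current value of the low-frequency boundary
    datum x(1-x) f -> theta * rho(t); quadrature routines use it to close
    integrals analytically on [0, x_1].  ``time`` is tau (2 N0 generations)
    elapsed since the solve began; ``time_gen`` is generations before
    present when the solve was driven by a demographic model.
    """

    grid: Grid
    values: np.ndarray
    params: ScenarioParams
    time: float = 0.0
    time_gen: float | None = None
    fixed_mass: float = 0.0
    lost_mass: float = 0.0
    injected_mass: float = 0.0
    boundary_theta: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.points.shape:
            raise ParameterError("values and grid shapes differ")
        self.values = v
        if self.boundary_theta is None:
            self.boundary_theta = self.params.theta

    def g(self) -> np.ndarray:
        """Transformed spectrum g = x(1-x) f at the grid nodes."""
        x = self.grid.points
        return x * (1.0 - x) * self.values

    def copy(self) -> "FrequencySpectrum":
        return FrequencySpectrum(
            grid=self.grid, values=self.values.copy(), params=self.params,
            time=self.time, time_gen=self.time_gen,
            fixed_mass=self.fixed_mass, lost_mass=self.lost_mass,
            injected_mass=self.injected_mass,
            boundary_theta=self.boundary_theta,
        )

    def segregating_mass(self) -> float:
        """Cell-integrated expected number of segregating sites on the grid."""
        return float(self.grid.widths @ self.values)


@dataclass(frozen=True)
class SolverConfig:
    """Time step (units of 2 N0 generations), grid, and scheme options."""

    dt: float = 1e-3
    n_grid: int = 2000
    refinement: float = 3.0
    snapshot_gens: tuple[float, ...] = ()
    theta_scheme: float = 0.5  # 0.5 Crank-Nicolson, 1.0 backward Euler
    rannacher_steps: int = 2   # backward-Euler steps after discontinuities
    # Within exponential epochs the step is shortened so rho changes by at
    # most this many e-foldings per step; recent human growth runs at
    # hundreds of e-foldings per 2 N0 generations, far faster than the
    # default dt resolves.
    max_rho_efold_per_step: float = 0.1

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ParameterError("dt must be positive")
        if not 0.5 <= self.theta_scheme <= 1.0:
            raise ParameterError("theta_scheme must lie in [0.5, 1]")

    def make_grid(self) -> Grid:
        return make_grid(self.n_grid, self.refinement)


def _bernoulli(z: np.ndarray) -> np.ndarray:
    """B(z) = z / (e^z - 1), evaluated stably for small and large |z|."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-5
    zs = z[small]
    out[small] = 1.0 - zs / 2.0 + zs**2 / 12.0
    mid = ~small & (np.abs(z) < 700.0)
    out[mid] = z[mid] / np.expm1(z[mid])
    big = ~small & ~mid
    out[big] = np.where(z[big] > 0, 0.0, -z[big])
    return out


def _equilibrium_kernel(a: float, x: np.ndarray) -> np.ndarray:
    """(e^{-a x} - e^{-a}) / (1 - e^{-a}) without overflow for any sign of a."""
    if abs(a) < 1e-8:
        return 1.0 - x
    if a > 0:
        return (np.exp(-a * x) - math.exp(-a)) / (-math.expm1(-a))
    # a < 0: divide numerator and denominator by e^{-a} to avoid overflow
    return np.expm1(a * (1.0 - x)) / math.expm1(a)


def equilibrium_spectrum(
    params: ScenarioParams, grid: Grid, rho: float = 1.0
) -> FrequencySpectrum:
    """Closed-form equilibrium spectrum at constant relative size ``rho``.

    For a population held at size rho * N0 the stationary solution is

        f(x) = theta rho (e^{-2 S rho x} - e^{-2 S rho}) /
               ((1 - e^{-2 S rho}) x (1 - x)),

    which reduces to the neutral f(x) = theta rho / x as S -> 0 and
    satisfies the boundary datum x(1-x) f -> theta rho.  The local scaled
    coefficient is S * rho because selection per generation is fixed while
    the drift clock runs at 1 / (2 N0 rho).
    """
    if not rho > 0:
        raise ParameterError("rho must be positive")
    x = grid.points
    kernel = _equilibrium_kernel(2.0 * params.S * rho, x)
    values = params.theta * rho * kernel / (x * (1.0 - x))
    if not np.all(np.isfinite(values)):
        raise SolverInstabilityError("equilibrium spectrum overflowed")
    return FrequencySpectrum(
        grid=grid, values=values, params=params,
        boundary_theta=params.theta * rho,
    )


def equilibrium_heterozygosity(S: float, theta: float, rho: float = 1.0) -> float:
    """Closed-form expected heterozygosity int 2 x(1-x) f dx at equilibrium.

    Equals 2 theta rho [ (1 - e^{-a})/a - e^{-a} ] / (1 - e^{-a}) with
    a = 2 S rho; the neutral limit is theta * rho and the strong-selection
    (mutation-selection balance) limit is theta / S.
    """
    a = 2.0 * S * rho
    if abs(a) < 1e-8:
        return theta * rho
    em = -math.expm1(-a)  # 1 - e^{-a}
    return 2.0 * theta * rho * (em / a - math.exp(-a)) / em


class _Stepper:
    """Tridiagonal theta-scheme stepper on a fixed grid.

    Faces are numbered 0..M; node i (0-based) lies between faces i and
    i + 1.  The semidiscrete system is w_i df_i/dt = J_i - J_{i+1} with
    J_k = c_l[k] g_{k-1} - c_r[k] g_k (g_{-1} -> boundary datum, g_M -> 0).
    """

    def __init__(self, grid: Grid, params: ScenarioParams,
                 mutation_on: bool) -> None:
        self.grid = grid
        self.params = params
        self.mutation_on = mutation_on
        x = grid.points
        self.a = x * (1.0 - x)  # g = a * f
        self.w = grid.widths
        self.h = grid.spacings
        self.M = grid.n_points

    def face_coeffs(self, rho: float) -> tuple[np.ndarray, np.ndarray]:
        """(c_l, c_r) with J_face = c_l g_left - c_r g_right.

        Scharfetter-Gummel: J = (D/h) [B(P) g_l - B(-P) g_r] with
        D = 1/(2 rho) and Peclet number P = 2 rho S h.
        """
        D = 1.0 / (2.0 * rho)
        P = 2.0 * rho * self.params.S * self.h
        c_l = (D / self.h) * _bernoulli(P)
        c_r = (D / self.h) * _bernoulli(-P)
        return c_l, c_r

    def assemble(self, rho: float):
        """Tridiagonal L (as sub/diag/sup) and source b: w df/dt = L f + b."""
        c_l, c_r = self.face_coeffs(rho)
        a, M = self.a, self.M
        diag = -(c_r[:M] + c_l[1:]) * a
        sub = np.zeros(M)   # coefficient of f_{i-1} in row i
        sub[1:] = c_l[1:M] * a[: M - 1]
        sup = np.zeros(M)   # coefficient of f_{i+1} in row i
        sup[: M - 1] = c_r[1:M] * a[1:]
        b = np.zeros(M)
        if self.mutation_on:
            b[0] = c_l[0] * self.params.theta * rho
        return sub, diag, sup, b, (c_l, c_r)

    @staticmethod
    def _apply(sub, diag, sup, f):
        Lf = diag * f
        Lf[1:] += sub[1:] * f[:-1]
        Lf[:-1] += sup[:-1] * f[1:]
        return Lf

    def boundary_fluxes(self, f: np.ndarray, rho: float,
                        coeffs) -> tuple[float, float]:
        """(J at x -> 0, J at x -> 1); J > 0 flows toward x = 1."""
        c_l, c_r = coeffs
        g = self.a * f
        g_b = self.params.theta * rho if self.mutation_on else 0.0
        j0 = c_l[0] * g_b - c_r[0] * g[0]
        j1 = c_l[-1] * g[-1]
        return float(j0), float(j1)

    def step(self, f: np.ndarray, rho_old: float, rho_new: float,
             dt: float, theta_s: float) -> tuple[np.ndarray, float, float]:
        """One theta-scheme step; returns (f_new, time-mean J0, J1)."""
        M = self.M
        sub_n, diag_n, sup_n, b_n, co_n = self.assemble(rho_new)
        rhs = (self.w / dt) * f + theta_s * b_n
        if theta_s < 1.0:
            sub_o, diag_o, sup_o, b_o, co_o = self.assemble(rho_old)
            rhs += (1.0 - theta_s) * (
                self._apply(sub_o, diag_o, sup_o, f) + b_o
            )
        ab = np.zeros((3, M))
        ab[0, 1:] = -theta_s * sup_n[: M - 1]
        ab[1, :] = self.w / dt - theta_s * diag_n
        ab[2, : M - 1] = -theta_s * sub_n[1:]
        f_new = solve_banded((1, 1), ab, rhs)
        j0, j1 = self.boundary_fluxes(f_new, rho_new, co_n)
        if theta_s < 1.0:
            j0_o, j1_o = self.boundary_fluxes(f, rho_old, co_o)
            j0 = theta_s * j0 + (1.0 - theta_s) * j0_o
            j1 = theta_s * j1 + (1.0 - theta_s) * j1_o
        return f_new, j0, j1


def _clip_negative(f: np.ndarray, step_label: str) -> np.ndarray:
    if not np.all(np.isfinite(f)):
        raise SolverInstabilityError(f"non-finite spectrum at {step_label}")
    fmax = float(np.max(f, initial=0.0))
    fmin = float(np.min(f, initial=0.0))
    if fmin < -NEG_TOL * max(fmax, 1.0):
        raise SolverInstabilityError(
            f"negative spectrum value {fmin:.3e} (max {fmax:.3e}) at {step_label}"
        )
    if fmin < 0.0:
        logger.debug("clipping tiny negative values at %s", step_label)
        f = np.where(f < 0.0, 0.0, f)
    return f


def solve(
    initial: FrequencySpectrum,
    model: DemographicModel,
    config: SolverConfig,
    t_start_gen: float | None = None,
    t_end_gen: float = 0.0,
    mutation_on: bool = True,
) -> list[FrequencySpectrum]:
    """Advance ``initial`` through ``model`` from ``t_start_gen`` (default:
    the model's oldest boundary) to ``t_end_gen`` generations before present.

    Returns snapshots at the requested ``config.snapshot_gens`` times inside
    the window (hit to within one time step) plus always the final state.
    Fixation, loss, and injection masses accumulate on the returned spectra;
    ``initial`` is not modified.
    """
    if t_start_gen is None:
        t_start_gen = model.start_gen
    if not t_start_gen > t_end_gen:
        raise ParameterError("t_start_gen must exceed t_end_gen")
    if t_start_gen > model.start_gen or t_end_gen < 0:
        raise ParameterError("solve window outside the model span")

    two_N0 = 2.0 * model.N0
    stepper = _Stepper(initial.grid, initial.params, mutation_on)

    # Segment the window at epoch boundaries so size discontinuities align
    # with step boundaries.
    bounds = sorted(
        {float(t_start_gen), float(t_end_gen)}
        | {b for b in model.boundaries() if t_end_gen < b < t_start_gen},
        reverse=True,
    )
    snapshot_gens = sorted(
        {g for g in config.snapshot_gens if t_end_gen <= g <= t_start_gen},
        reverse=True,
    )

    state = initial.copy()
    state.time_gen = t_start_gen
    state.boundary_theta = (
        initial.params.theta * model.rho_at(t_start_gen) if mutation_on else 0.0
    )
    f = state.values
    snapshots: list[FrequencySpectrum] = []
    snap_idx = 0
    # Snapshot requests at (or older than) the start return the initial state.
    while (snap_idx < len(snapshot_gens)
           and snapshot_gens[snap_idx] >= t_start_gen - 1e-9):
        snapshots.append(state.copy())
        snap_idx += 1

    for seg_start, seg_end in zip(bounds[:-1], bounds[1:]):
        seg_tau = (seg_start - seg_end) / two_N0
        epoch = model.epoch_at(0.5 * (seg_start + seg_end))
        dt_max = config.dt
        if epoch.growth_rate != 0.0:
            rate_tau = abs(epoch.growth_rate) * two_N0
            dt_max = min(dt_max, config.max_rho_efold_per_step / rate_tau)
        n_steps = max(1, math.ceil(seg_tau / dt_max))
        dt = seg_tau / n_steps
        # A segment starting at a size discontinuity (or at the solve start,
        # where the initial condition need not match the operator) gets
        # backward-Euler startup steps.
        if seg_start < model.start_gen:
            eps = 1e-6
            discontinuous = not math.isclose(
                model.rho_at(min(seg_start + eps, model.start_gen)),
                model.rho_at(seg_start),
                rel_tol=1e-9,
            )
        else:
            discontinuous = True
        for k in range(n_steps):
            t_old = seg_start - k * dt * two_N0
            t_new = max(seg_start - (k + 1) * dt * two_N0, seg_end)
            rho_old = model.rho_at(t_old)
            rho_new = model.rho_at(t_new)
            theta_s = (
                1.0
                if (discontinuous and k < config.rannacher_steps)
                else config.theta_scheme
            )
            f, j0, j1 = stepper.step(f, rho_old, rho_new, dt, theta_s)
            f = _clip_negative(
                f, f"t={t_new:.6g} gen (segment [{seg_start:g}, {seg_end:g}])"
            )
            state.values = f
            state.time += dt
            state.time_gen = t_new
            state.fixed_mass += dt * j1
            if j0 >= 0.0:
                state.injected_mass += dt * j0
            else:
                state.lost_mass += dt * (-j0)
            state.boundary_theta = (
                initial.params.theta * rho_new if mutation_on else 0.0
            )
            while (snap_idx < len(snapshot_gens)
                   and t_new <= snapshot_gens[snap_idx] + 1e-9):
                snapshots.append(state.copy())
                snap_idx += 1

    if not snapshots or snapshots[-1].time_gen != state.time_gen:
        snapshots.append(state.copy())
    return snapshots


def no_selection_counterfactual(
    initial: FrequencySpectrum,
    model: DemographicModel,
    config: SolverConfig,
    keep_mutation: bool = True,
    t_start_gen: float | None = None,
    t_end_gen: float = 0.0,
) -> list[FrequencySpectrum]:
    """Solve with selection switched off (S = 0) over the given window.

    With ``keep_mutation`` False the boundary injection theta * rho(t) is
    zeroed as well, so segregating mass can only decay.  Compose with a
    preceding :func:`solve` call to switch selection off at a particular
    demographic event while retaining the selected history before it.

    Zeroing the boundary datum collapses the 1/x boundary layer of the
    incoming spectrum, a stiff non-smooth transient; the no-mutation
    variant therefore steps fully implicitly (backward Euler), which is
    monotone, rather than with Crank-Nicolson.
    """
    neutral = initial.copy()
    neutral.params = initial.params.replace(S=0.0)
    if not keep_mutation:
        config = dataclasses.replace(config, theta_scheme=1.0)
    return solve(
        neutral, model, config,
        t_start_gen=t_start_gen, t_end_gen=t_end_gen,
        mutation_on=keep_mutation,
    )


def write_snapshots(snapshots: list[FrequencySpectrum], path) -> None:
    """Export snapshots as a TSV with one row per (time, grid point)."""
    import pandas as pd

    frames = []
    for snap in snapshots:
        frames.append(pd.DataFrame({
            "time_coal": snap.time,
            "time_gen": snap.time_gen if snap.time_gen is not None else np.nan,
            "x": snap.grid.points,
            "f": snap.values,
            "fixed_mass": snap.fixed_mass,
            "lost_mass": snap.lost_mass,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
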