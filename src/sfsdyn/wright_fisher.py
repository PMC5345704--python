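"""Discrete Wright-Fisher expected-SFS engine for small populations.

This propagates the *expected* number of sites at each derived-allele count
i = 1..2N-1 through the exact Wright-Fisher Markov transition kernel with
genic selection (genotype fitnesses 1, 1-s, 1-2s), rather than simulating
stochastic replicates: the diffusion solver predicts expectations, so the
deterministic propagation is the matching brute-force reference without
Monte-Carlo noise.  Mutational input adds 2 N l mu expected new singletons
per generation; probability mass reaching counts 0 and 2N accrues to lost
and fixed totals, so the per-generation mass balance

    injected = d(segregating) + d(fixed) + d(lost)

holds to roundoff.  Dense kernels are practical only for small populations;
a guard refuses 2N > 1000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .diffusion import FrequencySpectrum, ParameterError, ScenarioParams

__all__ = [
    "WFState",
    "wf_step",
    "wf_run",
    "wf_equilibrium_init",
    "selection_map",
    "transition_matrix",
    "wf_heterozygosity",
    "wf_derived_burden",
    "wf_prob_polymorphic",
    "compare_to_diffusion",
]

MAX_TWO_N = 1000


@dataclass
class WFState:
    """Expected site counts by derived-allele count in a population of
    ``two_N`` chromosomes, plus absorbed fixation/loss mass."""

    two_N: int
    counts: np.ndarray  # length two_N - 1, index i -> derived count i + 1
    s: float
    l_mu: float         # l * mu, expected mutations per chromosome per gen
    fixed_mass: float = 0.0
    lost_mass: float = 0.0
    injected_mass: float = 0.0
    generation: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (self.two_N - 1,):
            raise ParameterError("counts must have length two_N - 1")
        if self.s >= 0.5:
            raise ParameterError("selection model requires s < 1/2")
        if self.two_N > MAX_TWO_N:
            raise ParameterError(
                f"dense kernel limited to 2N <= {MAX_TWO_N}, got {self.two_N}"
            )
        self.counts = c

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(1, self.two_N) / self.two_N

    @property
    def theta_wf(self) -> float:
        return 2.0 * self.two_N * self.l_mu  # 4 N l mu

    def copy(self) -> "WFState":
        return WFState(
            two_N=self.two_N, counts=self.counts.copy(), s=self.s,
            l_mu=self.l_mu, fixed_mass=self.fixed_mass,
            lost_mass=self.lost_mass, injected_mass=self.injected_mass,
            generation=self.generation,
        )


def selection_map(x: np.ndarray, s: float) -> np.ndarray:
    """Deterministic post-selection frequency under genotype fitnesses
    (1, 1-s, 1-2s): x* = x (1 - s(1 + x)) / (1 - 2 s x)."""
    x = np.asarray(x, dtype=float)
    return x * (1.0 - s * (1.0 + x)) / (1.0 - 2.0 * s * x)


def transition_matrix(two_N_from: int, two_N_to: int, s: float) -> np.ndarray:
    """Rows: source counts 1..two_N_from - 1; columns: destination counts
    0..two_N_to.  Selection acts before binomial resampling to the
    destination size (the destination size differs only at an instantaneous
    size change)."""
    if max(two_N_from, two_N_to) > MAX_TWO_N:
        raise ParameterError(f"dense kernel limited to 2N <= {MAX_TWO_N}")
    x = np.arange(1, two_N_from) / two_N_from
    x_star = selection_map(x, s)
    j = np.arange(0, two_N_to + 1)
    return binom.pmf(j[None, :], two_N_to, x_star[:, None])


def wf_equilibrium_init(two_N: int, s: float, l_mu: float) -> WFState:
    """Initialize expected counts from the diffusion equilibrium evaluated
    at the discrete frequencies (midpoint rule, cell width 1/2N)."""
    from .diffusion import _equilibrium_kernel

    params = ScenarioParams.from_rates(s=s, two_N0=float(two_N), mu=l_mu, l=1.0)
    x = np.arange(1, two_N) / two_N
    kernel = _equilibrium_kernel(2.0 * params.S, x)
    f_vals = params.theta * kernel / (x * (1.0 - x))
    return WFState(two_N=two_N, counts=f_vals / two_N, s=s, l_mu=l_mu)


def wf_stationary_state(
    two_N: int, s: float, l_mu: float, burn_factor: int = 10
) -> WFState:
    """Burn the chain in at constant size until quasi-stationary.

    Starts from the diffusion equilibrium evaluated on the lattice and runs
    ``burn_factor * 2N`` generations, long past the ~2N-generation
    relaxation time, so the result is the Wright-Fisher model's own
    expected-SFS equilibrium rather than the diffusion's.  Absorbed-mass
    counters are reset to zero afterwards.
    """
    state = wf_equilibrium_init(two_N, s, l_mu)
    matrix = transition_matrix(two_N, two_N, s)
    for _ in range(burn_factor * two_N):
        state = wf_step(state, matrix)
    state.fixed_mass = state.lost_mass = state.injected_mass = 0.0
    state.generation = 0
    return state


def wf_step(state: WFState, matrix: np.ndarray | None = None) -> WFState:
    """Advance one generation: selection + binomial resampling applied to
    the expected-count vector, then mutational injection of 2 N l mu new
    singletons; absorbed mass accrues to lost/fixed."""
    out = state.copy()
    if matrix is None:
        matrix = transition_matrix(state.two_N, state.two_N, state.s)
    dist = state.counts @ matrix  # expected counts over destination 0..2N
    out.lost_mass += float(dist[0])
    out.fixed_mass += float(dist[-1])
    new = dist[1:-1].copy()
    injection = state.two_N * state.l_mu
    new[0] += injection
    out.injected_mass += injection
    out.counts = new
    out.generation += 1
    return out


def resize(state: WFState, two_N_new: int) -> WFState:
    """Instantaneous size change via one binomial resampling to the new
    size (no selection applied in the resampling itself)."""
    kernel = transition_matrix(state.two_N, two_N_new, 0.0)
    dist = state.counts @ kernel
    out = WFState(
        two_N=two_N_new, counts=dist[1:-1].copy(), s=state.s, l_mu=state.l_mu,
        fixed_mass=state.fixed_mass + float(dist[-1]),
        lost_mass=state.lost_mass + float(dist[0]),
        injected_mass=state.injected_mass, generation=state.generation,
    )
    return out


def wf_run(
    schedule: list[tuple[int, int]],
    s: float,
    l_mu: float,
    init: WFState | None = None,
    record_every: int | None = None,
) -> list[WFState]:
    """Drive the expected-count vector across a size schedule.

    ``schedule`` is a list of (two_N, generations) phases; sizes change
    instantaneously between phases by binomial resampling.  Returns recorded
    states (every ``record_every`` generations if set, plus phase ends).
    """
    if not schedule:
        raise ParameterError("empty schedule")
    if init is None:
        init = wf_equilibrium_init(schedule[0][0], s, l_mu)
    state = init.copy()
    recorded: list[WFState] = [state.copy()]
    for two_N, n_gen in schedule:
        if two_N != state.two_N:
            state = resize(state, two_N)
        matrix = transition_matrix(two_N, two_N, s)
        for g in range(n_gen):
            state = wf_step(state, matrix)
            if record_every and state.generation % record_every == 0:
                recorded.append(state.copy())
    if recorded[-1].generation != state.generation:
        recorded.append(state.copy())
    return recorded


def wf_heterozygosity(state: WFState) -> float:
    x = state.freqs
    return float(np.sum(2.0 * x * (1.0 - x) * state.counts))


def wf_derived_burden(state: WFState, include_fixed: bool = True) -> float:
    x = state.freqs
    seg = float(np.sum(x * state.counts))
    return 2.0 * (seg + (state.fixed_mass if include_fixed else 0.0))


def wf_derived_hom(state: WFState, include_fixed: bool = True) -> float:
    x = state.freqs
    seg = float(np.sum(x**2 * state.counts))
    return seg + (state.fixed_mass if include_fixed else 0.0)


def wf_prob_polymorphic(state: WFState, n: int) -> float:
    """Expected polymorphic sites in a sample of n chromosomes drawn with
    replacement (matching the diffusion projection)."""
    x = state.freqs
    phi = 1.0 - x**n - (1.0 - x) ** n
    return float(np.sum(phi * state.counts))


def wf_segregating(state: WFState) -> float:
    return float(np.sum(state.counts))


def _truncated_integral(snap: FrequencySpectrum, phi, lo: float, hi: float
                        ) -> float:
    """Trapezoid quadrature of phi * f over [lo, hi] on the snapshot grid,
    with interpolated integrand values at the cut points."""
    x = snap.grid.points
    h = phi(x) * snap.values
    m = (x >= lo) & (x <= hi)
    xe = np.concatenate(([lo], x[m], [hi]))
    he = np.concatenate(([np.interp(lo, x, h)], h[m], [np.interp(hi, x, h)]))
    return float(np.trapezoid(he, xe))


def compare_to_diffusion(
    wf_states: list[WFState],
    snapshots: list[FrequencySpectrum],
    two_N0: float,
    sample_n: int = 20,
    lattice_match: bool = True,
) -> pd.DataFrame:
    """Relative differences between matched-time WF states and diffusion
    snapshots for heterozygosity, derived burden, and P_n.

    WF generation g corresponds to diffusion time tau = g / (2 N0); states
    whose times do not align within half a generation raise an error.

    With ``lattice_match`` (default) the diffusion integrals are restricted
    to [1/(4N), 1 - 1/(4N)]: lattice count i corresponds to the frequency
    cell (i - 1/2, i + 1/2) / 2N, so continuum mass below half a lattice
    cell maps to the monomorphic classes and should not be counted against
    the discrete model.
    """
    from . import summaries

    if len(wf_states) != len(snapshots):
        raise ParameterError(
            f"{len(wf_states)} WF states vs {len(snapshots)} snapshots"
        )
    rows = []
    for st, snap in zip(wf_states, snapshots):
        tau_wf = st.generation / two_N0
        if abs(tau_wf - snap.time) * two_N0 > 0.51:
            raise ParameterError(
                f"time mismatch: WF gen {st.generation} vs diffusion tau "
                f"{snap.time:.6f} (2N0 = {two_N0})"
            )
        if lattice_match:
            lo = 1.0 / (4.0 * st.two_N)
            hi = 1.0 - lo
            n = sample_n
            d_het = _truncated_integral(
                snap, lambda x: 2.0 * x * (1.0 - x), lo, hi)
            d_bur = 2.0 * (_truncated_integral(snap, lambda x: x, lo, hi)
                           + snap.fixed_mass)
            d_pn = _truncated_integral(
                snap, lambda x: 1.0 - x**n - (1.0 - x) ** n, lo, hi)
        else:
            d_het = summaries.heterozygosity(snap)
            d_bur = summaries.derived_burden(snap)
            d_pn = summaries.prob_polymorphic(snap, sample_n)
        pairs = {
            "heterozygosity": (wf_heterozygosity(st), d_het),
            "derived_burden": (wf_derived_burden(st), d_bur),
            f"P_{sample_n}": (wf_prob_polymorphic(st, sample_n), d_pn),
        }
        for stat, (wf_val, diff_val) in pairs.items():
            denom = abs(diff_val) if diff_val != 0 else 1.0
            rows.append({
                "generation": st.generation,
                "tau": snap.time,
                "statistic": stat,
                "wf": wf_val,
                "diffusion": diff_val,
                "rel_diff": abs(wf_val - diff_val) / denom,
            })
    return pd.DataFrame(rows)
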