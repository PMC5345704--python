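"""Summaries of a frequency spectrum: sample SFS, heterozygosity, burden,
derived homozygosity, PN/PT, and equilibrium selection rates on PN/PT.

All population-to-sample projections assume binomial sampling with
replacement,

    E[q_{n,k}] = int_0^1 C(n,k) x^k (1-x)^{n-k} f(x) dx,

and all integrals against f use trapezoid quadrature on the solver grid
closed analytically at the boundaries: because x(1-x) f tends to the known
datum theta * rho at x -> 0 (and to 0 at x -> 1), the integrand
phi(x) f(x) = phi(x) g(x) / (x(1-x)) has finite limits at both endpoints
even though f itself diverges like 1/x.  Truncating instead would bias the
singleton-dominated statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln

from .diffusion import FrequencySpectrum, ParameterError

__all__ = [
    "SampleSFS",
    "PNPTResult",
    "RateParams",
    "integrate_against",
    "sample_sfs",
    "heterozygosity",
    "derived_burden",
    "derived_hom",
    "prob_polymorphic",
    "pn_pt",
    "pnpt_selection_rate_sample",
    "pnpt_selection_rate_population",
    "per_mb_scaling",
    "write_sample_sfs",
]


@dataclass(frozen=True)
class SampleSFS:
    """Expected sample SFS: E[q_{n,k}] for k = 1..n-1."""

    n: int
    expected_counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.expected_counts, dtype=float)
        if c.shape != (self.n - 1,):
            raise ParameterError("expected_counts must have length n - 1")
        object.__setattr__(self, "expected_counts", c)

    def total_polymorphic(self) -> float:
        return float(self.expected_counts.sum())


@dataclass(frozen=True)
class PNPTResult:
    """Expected polymorphic-site counts by mutation class at one sample size.

    ``ratio`` = PN / (PN + PS) is the proportion of sample variants in the
    deleterious (nonsynonymous-like) class.
    """

    sample_size: int
    PN: float
    PS: float

    @property
    def PT(self) -> float:
        return self.PN + self.PS

    @property
    def ratio(self) -> float:
        if self.PT == 0:
            raise ZeroDivisionError("PT = 0: PN/PT undefined")
        return self.PN / self.PT


@dataclass(frozen=True)
class RateParams:
    """Inputs to the equilibrium selection-rate formulas for PN/PT.

    ``theta_N`` is the population-scaled mutation rate to deleterious
    alleles; ``k`` the sample size in chromosomes (ignored by the
    whole-population formula).
    """

    S: float
    theta_N: float
    k: int = 2

    def __post_init__(self) -> None:
        if not self.theta_N > 0:
            raise ParameterError("theta_N must be positive")


def integrate_against(
    f: FrequencySpectrum,
    phi: Callable[[np.ndarray], np.ndarray],
    dphi0: float | None = None,
) -> float:
    """Trapezoid quadrature of int phi(x) f(x) dx with analytic endpoint
    closure.

    ``phi`` must vanish at x = 0 (all spectrum summaries used here do);
    ``dphi0`` is phi'(0), estimated numerically when omitted.  At x -> 0 the
    integrand tends to phi'(0) * g(0) with g(0) the boundary datum carried
    by the spectrum; at x -> 1 it tends to phi(1) * g(x_M) / (1 - x_M).
    """
    x = f.grid.points
    g_b = f.boundary_theta if f.boundary_theta is not None else 0.0
    if dphi0 is None:
        eps = 1e-9
        phi0 = float(np.asarray(phi(np.array([0.0]))).item())
        if abs(phi0) > 1e-12:
            raise ParameterError("phi must vanish at x = 0")
        dphi0 = float(np.asarray(phi(np.array([eps]))).item()) / eps
    interior = phi(x) * f.values
    g_last = x[-1] * (1.0 - x[-1]) * f.values[-1]
    phi1 = float(np.asarray(phi(np.array([1.0]))).item())
    h0 = dphi0 * g_b
    h1 = phi1 * g_last / (1.0 - x[-1])
    xe = np.concatenate(([0.0], x, [1.0]))
    he = np.concatenate(([h0], interior, [h1]))
    return float(np.trapezoid(he, xe))


def heterozygosity(f: FrequencySpectrum) -> float:
    """Expected heterozygous genotypes per individual, int 2 x(1-x) f dx."""
    return integrate_against(f, lambda x: 2.0 * x * (1.0 - x), dphi0=2.0)


def derived_burden(f: FrequencySpectrum, include_fixed: bool = True) -> float:
    """Expected derived alleles per diploid genome, 2 (int x f dx + fixed).

    ``include_fixed`` adds twice the fixation mass accumulated since the
    solve started; disable it to track the segregating component alone.
    """
    seg = integrate_against(f, lambda x: x, dphi0=1.0)
    return 2.0 * (seg + (f.fixed_mass if include_fixed else 0.0))


def derived_hom(f: FrequencySpectrum, include_fixed: bool = True) -> float:
    """Expected homozygous-derived genotypes per diploid,
    int x^2 f dx + fixed."""
    seg = integrate_against(f, lambda x: x**2, dphi0=0.0)
    return seg + (f.fixed_mass if include_fixed else 0.0)


def _poly_phi(n: int) -> Callable[[np.ndarray], np.ndarray]:
    def phi(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            one_minus = np.where(
                x < 1.0, np.expm1(n * np.log1p(-np.minimum(x, 1.0 - 1e-300))), -1.0
            )
            xn = np.where(x > 0.0, np.exp(n * np.log(np.maximum(x, 1e-300))), 0.0)
        return -one_minus - xn

    return phi


def prob_polymorphic(f: FrequencySpectrum, n: int) -> float:
    """Expected number of sites polymorphic in a sample of ``n``
    chromosomes, int (1 - x^n - (1-x)^n) f dx; nondecreasing in n."""
    if n < 2:
        raise ParameterError("sample size must be at least 2")
    return integrate_against(f, _poly_phi(n), dphi0=float(n))


def sample_sfs(f: FrequencySpectrum, n: int) -> SampleSFS:
    """Expected sample SFS by binomial projection of the spectrum.

    Binomial weights are evaluated in log space so sample sizes in the
    tens of thousands stay finite; entries are computed in blocks of k to
    bound memory.
    """
    if n < 2:
        raise ParameterError("sample size must be at least 2")
    x = f.grid.points
    logx = np.log(x)
    log1mx = np.log1p(-x)
    counts = np.empty(n - 1)
    ks = np.arange(1, n)
    log_binom = (gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1))
    g_b = f.boundary_theta if f.boundary_theta is not None else 0.0
    g_last = x[-1] * (1.0 - x[-1]) * f.values[-1]
    xe = np.concatenate(([0.0], x, [1.0]))
    block = max(1, int(2e7) // x.size)
    for lo in range(0, n - 1, block):
        hi = min(lo + block, n - 1)
        kb = ks[lo:hi, None]
        w = np.exp(log_binom[lo:hi, None] + kb * logx[None, :]
                   + (n - kb) * log1mx[None, :])
        he = np.empty((hi - lo, x.size + 2))
        he[:, 1:-1] = w * f.values[None, :]
        # phi'(0) = n for k = 1, else 0; phi(1) = 0 for all k < n
        he[:, 0] = np.where(ks[lo:hi] == 1, n * g_b, 0.0)
        he[:, -1] = 0.0 * g_last
        counts[lo:hi] = np.trapezoid(he, xe, axis=1)
    return SampleSFS(n=n, expected_counts=counts)


def pn_pt(
    fN: FrequencySpectrum, fS: FrequencySpectrum, n: int
) -> PNPTResult:
    """PN/PT at sample size ``n`` from a deleterious-class spectrum ``fN``
    and a neutral-class spectrum ``fS`` solved under the same demography.

    The mutation-class ratio is carried by the spectra's theta values
    (conventionally 2:1 deleterious:neutral).
    """
    PN = prob_polymorphic(fN, n)
    PS = prob_polymorphic(fS, n)
    return PNPTResult(sample_size=n, PN=PN, PS=PS)


def pnpt_selection_rate_sample(rp: RateParams, PN_k: float, PS_k: float
                               ) -> float:
    """Equilibrium rate of PN/PT change per 2N generations due to selection,
    for a sample of k chromosomes:

        -theta_N int (1 - x^k - (1-x)^k) 2 S^2 e^{-2Sx} / (1 - e^{-2S}) dx
            * PS_k / (PN_k + PS_k)^2.

    Always <= 0 for S > 0 (selection removes deleterious variants); the
    S -> 0 limit is 0.
    """
    S, k = rp.S, rp.k
    if S == 0.0:
        return 0.0
    denom = -np.expm1(-2.0 * S)

    def integrand(x: float) -> float:
        phi = 1.0 - x**k - (1.0 - x) ** k
        return phi * 2.0 * S**2 * np.exp(-2.0 * S * x) / denom

    val, _ = quad(integrand, 0.0, 1.0, limit=200,
                  points=[min(1.0, 1.0 / max(abs(S), 1.0))])
    return -rp.theta_N * val * PS_k / (PN_k + PS_k) ** 2


def pnpt_selection_rate_population(rp: RateParams, PN: float, PS: float
                                   ) -> float:
    """Whole-population analog: -S theta_N PS / (PN + PS)^2 per 2N
    generations."""
    if rp.S == 0.0:
        return 0.0
    return -rp.S * rp.theta_N * PS / (PN + PS) ** 2


def per_mb_scaling(
    raw_value: float,
    theta_solved: float,
    two_N0: float,
    mu: float = 1.2e-8,
    nonsyn_fraction: float = 2.0 / 3.0,
) -> float:
    """Rescale a statistic computed at ``theta_solved`` to a per-megabase,
    nonsynonymous-fraction value: linear in theta, with the per-Mb theta
    being 4 N0 * 1e6 * mu * nonsyn_fraction."""
    theta_mb = 2.0 * two_N0 * 1e6 * mu * nonsyn_fraction
    return raw_value * theta_mb / theta_solved


def write_sample_sfs(sfs: SampleSFS, path) -> None:
    import pandas as pd

    pd.DataFrame({
        "n": sfs.n,
        "k": np.arange(1, sfs.n),
        "expected_count": sfs.expected_counts,
    }).to_csv(path, sep="\t", index=False)
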