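"""Synthetic exome site tables with known ground truth.

Emulates the structure of a two-population exome aggregation call set
(an African-ancestry and a European-ancestry sample) so the empirical
pipeline can be exercised without any download: per-site derived-allele
counts in both samples, a conservation (GERP-like) score stochastically
monotone in the true selection coefficient, ancestral-state misassignment,
genotype missingness, and a quality pass/fail flag.

Sites are independent (Poisson random field): each mutation class (one
selection coefficient, or neutral) contributes a Poisson number of latent
sites; a latent site segregates in a population with probability
proportional to that population's solved spectrum mass, carries a
population frequency drawn from the normalized spectrum, or is fixed
derived with probability proportional to the accumulated fixation mass.
Frequencies are drawn independently across populations given the class —
joint two-population spectra are out of scope — so per-class *marginal*
summaries match the solved spectra while cross-population covariance at a
site is not modeled.

Sample counts are binomial given the population frequency and the number
of successfully called chromosomes.  The conservation score is
a + b*log10(s) + Normal(0, sigma) for selected sites and
Normal(mu0, sigma0) for neutral ones, so score bins mix neutral and
selected sites as real conservation-score bins do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffusion import FrequencySpectrum, ParameterError

__all__ = [
    "GerpModel",
    "MissingnessModel",
    "GeneratorConfig",
    "generate_sites",
    "write_site_table",
    "read_site_table",
    "SITE_TABLE_COLUMNS",
]

SITE_TABLE_COLUMNS = [
    "site_id", "gerp", "afr_der", "afr_called", "nfe_der", "nfe_called",
    "anc_known", "passed_qc", "true_s", "flipped",
]
# truth / bookkeeping columns that may be absent when reading real data
_OPTIONAL_COLUMNS = {"anc_known": True, "passed_qc": True,
                     "true_s": np.nan, "flipped": False}


class TableFormatError(ValueError):
    pass


@dataclass(frozen=True)
class GerpModel:
    """Score model: selected sites get a + b*log10(s) + N(0, sigma_sel);
    neutral sites get N(mu_neutral, sigma_neutral).

    Defaults place s = 1e-5..1e-2 at mean scores -3..3 with unit noise and
    neutral sites at 0 +/- 1.5, so neighbouring bins overlap substantially
    and bins mix neutral with selected sites, as real conservation-score
    bins do.
    """

    a: float = 7.0
    b: float = 2.0
    sigma_sel: float = 1.0
    mu_neutral: float = 0.0
    sigma_neutral: float = 1.5


@dataclass(frozen=True)
class MissingnessModel:
    """Per-site called-fraction model.

    Most sites are well covered (Beta(30, 2), mean ~0.94, drawn per
    population); a small fraction ``p_bad`` are hard-to-call in *both*
    populations (Beta(1, 9), mean 0.1), which is what the >90%-missing
    filter is meant to remove.
    """

    p_bad: float = 0.02
    good_alpha: float = 30.0
    good_beta: float = 2.0
    bad_alpha: float = 1.0
    bad_beta: float = 9.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic exome table.

    ``dfe`` maps selection coefficients to mixture weights; together with
    ``neutral_weight`` the weights must sum to 1 (default: one third
    neutral, two thirds deleterious, i.e. the conventional 2:1 ratio).
    Default sample sizes are desk-scale (2000 and 10,000 chromosomes);
    :meth:`exac_scale` returns the full-study preset (2 x 5203 and
    2 x 33,370 chromosomes).
    """

    n_sites_target: int = 50_000
    dfe: tuple[tuple[float, float], ...] = (
        (1e-5, 1.0 / 6), (1e-4, 1.0 / 6), (1e-3, 1.0 / 6), (1e-2, 1.0 / 6),
    )
    neutral_weight: float = 1.0 / 3
    afr_chroms: int = 2_000
    nfe_chroms: int = 10_000
    misassignment_rate: float = 0.01
    p_anc_known: float = 1.0
    p_fail_qc: float = 0.004
    gerp_model: GerpModel = field(default_factory=GerpModel)
    missingness: MissingnessModel = field(default_factory=MissingnessModel)
    seed: int = 0

    def __post_init__(self) -> None:
        w = [w for _, w in self.dfe] + [self.neutral_weight]
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ParameterError("DFE weights must be >= 0 and sum to 1")
        if min(self.afr_chroms, self.nfe_chroms) < 2:
            raise ParameterError("sample sizes must be at least 2 chromosomes")
        if not 0 <= self.misassignment_rate <= 1:
            raise ParameterError("misassignment_rate must be in [0, 1]")

    def exac_scale(self) -> "GeneratorConfig":
        import dataclasses

        return dataclasses.replace(
            self, afr_chroms=2 * 5_203, nfe_chroms=2 * 33_370
        )

    def class_labels(self) -> list[float]:
        """Selection coefficients of all classes; 0.0 denotes neutral."""
        return [s for s, _ in self.dfe] + [0.0]


def _spectrum_atoms(f: FrequencySpectrum) -> tuple[np.ndarray, np.ndarray, float]:
    """Grid frequencies, per-cell segregating mass, and fixed mass."""
    mass = f.grid.widths * f.values
    return f.grid.points, mass, float(f.fixed_mass)


def generate_sites(
    config: GeneratorConfig,
    spectra: dict[float, tuple[FrequencySpectrum, FrequencySpectrum]],
) -> pd.DataFrame:
    """Draw a synthetic site table from solved present-day spectra.

    ``spectra`` maps each selection coefficient in the config's DFE
    (0.0 for the neutral class) to the pair (African-like, European-like)
    frequency spectra solved at matched present time.  Returns the table
    with truth columns; sites with no derived allele observed in either
    sample are dropped (they would be invisible to a variant caller).
    """
    rng = np.random.default_rng(config.seed)
    weights = dict(config.dfe)
    weights[0.0] = weights.get(0.0, 0.0) + config.neutral_weight
    missing = [s for s in weights if s not in spectra and weights[s] > 0]
    if missing:
        raise ParameterError(f"no spectra supplied for classes {missing}")

    # The DFE weights apportion *mutational opportunity* (latent sites);
    # the common normalization C is chosen so the expected number of
    # sample-visible sites across classes is n_sites_target.  Visibility of
    # a latent site is 1 minus the probability that both samples draw zero
    # derived copies.
    class_info = {}
    for s_class, w in weights.items():
        if w == 0:
            continue
        f_afr, f_nfe = spectra[s_class]
        atoms = {"afr": _spectrum_atoms(f_afr), "nfe": _spectrum_atoms(f_nfe)}
        scale = max(m.sum() + fx for (_, m, fx) in atoms.values())
        p_invis = 1.0
        for pop, n_chrom in (("afr", config.afr_chroms),
                             ("nfe", config.nfe_chroms)):
            x, m, fx = atoms[pop]
            p_zero_freq = 1.0 - (m.sum() + fx) / scale
            p_no_draw = float(np.sum((m / scale) * (1.0 - x) ** n_chrom))
            p_invis *= p_zero_freq + p_no_draw
        class_info[s_class] = (atoms, scale, 1.0 - p_invis)
    yield_per_unit = sum(w * class_info[s][2] for s, w in weights.items()
                         if w > 0)
    if yield_per_unit <= 0:
        raise ParameterError("spectra yield no visible sites")
    C = config.n_sites_target / yield_per_unit

    frames = []
    mm = config.missingness
    gm = config.gerp_model
    for s_class, w in weights.items():
        if w == 0:
            continue
        n_sites = int(rng.poisson(w * C))
        if n_sites == 0:
            continue
        atoms, scale, _ = class_info[s_class]
        freqs = {}
        for pop, (x, m, fx) in atoms.items():
            u = rng.random(n_sites)
            p_seg = m.sum() / scale
            p_fix = fx / scale
            fr = np.zeros(n_sites)
            seg = u < p_seg
            fix = (u >= p_seg) & (u < p_seg + p_fix)
            if seg.any():
                idx = rng.choice(x.size, size=int(seg.sum()), p=m / m.sum())
                fr[seg] = x[idx]
            fr[fix] = 1.0
            freqs[pop] = fr

        bad = rng.random(n_sites) < mm.p_bad
        called = {}
        for pop, total in (("afr", config.afr_chroms), ("nfe", config.nfe_chroms)):
            frac = np.where(
                bad,
                rng.beta(mm.bad_alpha, mm.bad_beta, n_sites),
                rng.beta(mm.good_alpha, mm.good_beta, n_sites),
            )
            called[pop] = np.round(frac * total).astype(int)

        der = {
            pop: rng.binomial(called[pop], freqs[pop]) for pop in ("afr", "nfe")
        }

        if s_class > 0:
            gerp = gm.a + gm.b * np.log10(s_class) + rng.normal(
                0.0, gm.sigma_sel, n_sites)
        else:
            gerp = rng.normal(gm.mu_neutral, gm.sigma_neutral, n_sites)

        flipped = rng.random(n_sites) < config.misassignment_rate
        for pop in ("afr", "nfe"):
            der[pop] = np.where(flipped, called[pop] - der[pop], der[pop])

        frames.append(pd.DataFrame({
            "gerp": gerp,
            "afr_der": der["afr"],
            "afr_called": called["afr"],
            "nfe_der": der["nfe"],
            "nfe_called": called["nfe"],
            "anc_known": rng.random(n_sites) < config.p_anc_known,
            "passed_qc": rng.random(n_sites) >= config.p_fail_qc,
            "true_s": s_class,
            "flipped": flipped,
        }))

    table = pd.concat(frames, ignore_index=True)
    visible = (table.afr_der > 0) | (table.nfe_der > 0)
    table = table[visible].reset_index(drop=True)
    table.insert(0, "site_id", np.arange(len(table)))
    return table


def write_site_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in SITE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise TableFormatError(f"site table missing columns {missing}")
    table[SITE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_site_table(path) -> pd.DataFrame:
    """Read a site-table TSV; truth columns are optional.

    Raises :class:`TableFormatError` naming the offending line for rows
    that fail validation (negative or inconsistent counts).
    """
    try:
        table = pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc
    required = [c for c in SITE_TABLE_COLUMNS if c not in _OPTIONAL_COLUMNS]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    for col, default in _OPTIONAL_COLUMNS.items():
        if col not in table.columns:
            table[col] = default
    for pop in ("afr", "nfe"):
        der, cal = table[f"{pop}_der"], table[f"{pop}_called"]
        bad = (der < 0) | (cal < 0) | (der > cal)
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, after the header
            raise TableFormatError(
                f"{path}: inconsistent {pop} counts at line {line}"
            )
    return table[SITE_TABLE_COLUMNS]
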