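"""Exome summary pipeline: polarization, missingness filtering, GERP
binning, per-bin summaries with bootstrap CIs, and the GERP burden.

Operates on the site-table layout produced by :mod:`sfsdyn.synth` (or
converted from a VCF externally): per-site derived and called chromosome
counts for an African-ancestry (``afr``) and a European-ancestry (``nfe``)
sample plus a conservation score.  All estimators are plug-in: with
p = derived/called per population, per-site heterozygosity is 2p(1-p),
derived homozygosity p^2, and derived allele frequency p; finite-sample
corrections are O(1/called) and are not applied.  Confidence intervals are
percentile bootstraps resampling sites within a bin (paired across
populations, so between-population differences inherit the pairing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import ParameterError

__all__ = [
    "GERPBinning",
    "polarize",
    "filter_missing",
    "filter_qc",
    "assign_bins",
    "bin_summaries",
    "gerp_burden",
    "CATCH_ALL",
]

# bin index used for the scores < catch_all_below bin
CATCH_ALL = -1


@dataclass(frozen=True)
class GERPBinning:
    """Equal-width bins over the observed score range at or above the
    catch-all threshold, plus one catch-all bin for scores below it.

    Scores below ``catch_all_below`` (default -1.8; a mix of highly
    constrained and poorly aligned sites in real data) go to the separate
    catch-all bin with index -1; the threshold itself belongs to the
    regular bins (the rule is strictly less-than).
    """

    edges: np.ndarray  # n_bins + 1 ascending edges
    catch_all_below: float = -1.8

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    def labels(self) -> list[str]:
        out = [f"<{self.catch_all_below:g}"]
        out += [f"({self.edges[i]:.3g}, {self.edges[i + 1]:.3g}]"
                for i in range(self.n_bins)]
        return out


def polarize(table: pd.DataFrame) -> pd.DataFrame:
    """Orient derived-allele counts using the ancestral call when present.

    Where the ancestral state is known (``anc_known``) the recorded
    derived counts are trusted as-is.  Otherwise the highest-frequency
    allele (by combined frequency across both samples) is assigned
    ancestral and counts are swapped accordingly; exact ties keep the
    recorded orientation.  Sites with no called chromosomes in either
    sample are dropped with a warning.  Adds a ``polarity_swapped`` column.
    """
    table = table.copy()
    called_total = table.afr_called + table.nfe_called
    empty = called_total == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} all-missing sites")
        table = table[~empty].copy()
        called_total = called_total[~empty]
    combined = (table.afr_der + table.nfe_der) / called_total
    swap = (~table.anc_known.astype(bool)) & (combined > 0.5)
    for pop in ("afr", "nfe"):
        der = table[f"{pop}_der"].to_numpy().copy()
        cal = table[f"{pop}_called"].to_numpy()
        der[swap.to_numpy()] = (cal - der)[swap.to_numpy()]
        table[f"{pop}_der"] = der
    table["polarity_swapped"] = swap.to_numpy()
    return table


def filter_missing(
    table: pd.DataFrame,
    afr_total: int | None = None,
    nfe_total: int | None = None,
    threshold: float = 0.90,
    mode: str = "and",
) -> tuple[pd.DataFrame, dict]:
    """Remove sites with missing data above ``threshold`` in both groups.

    Missingness per group is 1 - called/total chromosomes; totals default
    to the per-group maximum observed in the table.  ``mode`` "and"
    (default) removes a site only when both groups exceed the threshold —
    the literal reading of "missing in both groups"; "or" removes when
    either does.  Idempotent.  Returns (filtered table, report).
    """
    if mode not in ("and", "or"):
        raise ParameterError("mode must be 'and' or 'or'")
    afr_total = int(table.afr_called.max()) if afr_total is None else afr_total
    nfe_total = int(table.nfe_called.max()) if nfe_total is None else nfe_total
    miss_afr = 1.0 - table.afr_called / afr_total
    miss_nfe = 1.0 - table.nfe_called / nfe_total
    high_afr = miss_afr > threshold
    high_nfe = miss_nfe > threshold
    drop = (high_afr & high_nfe) if mode == "and" else (high_afr | high_nfe)
    report = {
        "n_input": int(len(table)),
        "n_removed": int(drop.sum()),
        "n_retained": int((~drop).sum()),
        "threshold": threshold,
        "mode": mode,
    }
    return table[~drop].reset_index(drop=True), report


def filter_qc(table: pd.DataFrame) -> pd.DataFrame:
    """Keep sites whose upstream variant-quality filter passed."""
    if "passed_qc" not in table.columns:
        return table
    return table[table.passed_qc.astype(bool)].reset_index(drop=True)


def assign_bins(
    table: pd.DataFrame,
    n_bins: int = 20,
    catch_all_below: float = -1.8,
) -> tuple[GERPBinning, np.ndarray]:
    """Equal-width score bins over the observed range >= the catch-all
    threshold; scores below it get bin index -1.

    Bins are right-closed (ties at an internal edge fall to the lower bin;
    the observed maximum falls in the last bin).  A degenerate range (all
    remaining scores equal) falls back to a single bin with a warning.
    Empty bins are permitted.
    """
    scores = table.gerp.to_numpy(dtype=float)
    regular = scores >= catch_all_below
    if not regular.any():
        raise ParameterError(
            f"no sites with score >= {catch_all_below}; cannot place bins"
        )
    lo, hi = scores[regular].min(), scores[regular].max()
    if lo == hi:
        warnings.warn("degenerate score range; using a single bin")
        edges = np.array([lo, np.nextafter(hi, np.inf)])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.full(scores.size, CATCH_ALL, dtype=int)
    # right-closed bins: index j when edges[j] < score <= edges[j+1],
    # with the minimum clamped into the first bin
    reg_idx = np.digitize(scores[regular], edges, right=True) - 1
    idx[regular] = np.clip(reg_idx, 0, edges.size - 2)
    return GERPBinning(edges=edges, catch_all_below=catch_all_below), idx


def _site_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Per-site plug-in estimates for both populations (NaN if uncalled)."""
    out = pd.DataFrame(index=table.index)
    for pop in ("afr", "nfe"):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(
                table[f"{pop}_called"] > 0,
                table[f"{pop}_der"] / table[f"{pop}_called"],
                np.nan,
            )
        out[f"{pop}_het"] = 2.0 * p * (1.0 - p)
        out[f"{pop}_hom"] = p**2
        out[f"{pop}_dfreq"] = p
    return out


_STATS = ("het", "hom", "dfreq")


def bin_summaries(
    table: pd.DataFrame,
    binning: GERPBinning,
    bin_idx: np.ndarray,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bin means of heterozygosity, derived homozygosity, and derived
    frequency for each population, their afr - nfe differences, and
    percentile bootstrap CIs resampling sites within the bin.

    Bins with fewer than two sites get point estimates with NaN CIs and
    ``ci_defined`` False.  Rows are ordered catch-all first, then
    ascending score bins.
    """
    rng = np.random.default_rng(seed)
    stats = _site_stats(table)
    alpha = (1.0 - ci) / 2.0
    rows = []
    order = [CATCH_ALL] + list(range(binning.n_bins))
    labels = binning.labels()
    for pos, b in enumerate(order):
        in_bin = bin_idx == b
        n_sites = int(in_bin.sum())
        row = {
            "bin": labels[pos],
            "bin_lo": (-np.inf if b == CATCH_ALL else binning.edges[b]),
            "bin_hi": (binning.catch_all_below if b == CATCH_ALL
                       else binning.edges[b + 1]),
            "n_sites": n_sites,
            "ci_defined": n_sites >= 2,
        }
        if n_sites == 0:
            for stat in _STATS:
                for key in (f"afr_{stat}", f"nfe_{stat}", f"diff_{stat}"):
                    row[key] = np.nan
                    row[f"{key}_lo"] = row[f"{key}_hi"] = np.nan
            rows.append(row)
            continue
        sub = stats[in_bin]
        point = {}
        for stat in _STATS:
            a = np.nanmean(sub[f"afr_{stat}"])
            n = np.nanmean(sub[f"nfe_{stat}"])
            point[f"afr_{stat}"] = a
            point[f"nfe_{stat}"] = n
            point[f"diff_{stat}"] = a - n
        row.update(point)
        if n_sites >= 2:
            arr = sub.to_numpy()
            cols = {c: i for i, c in enumerate(sub.columns)}
            boots = {k: np.empty(n_boot) for k in point}
            for r in range(n_boot):
                take = rng.integers(0, n_sites, n_sites)
                res = arr[take]
                for stat in _STATS:
                    a = np.nanmean(res[:, cols[f"afr_{stat}"]])
                    n = np.nanmean(res[:, cols[f"nfe_{stat}"]])
                    boots[f"afr_{stat}"][r] = a
                    boots[f"nfe_{stat}"][r] = n
                    boots[f"diff_{stat}"][r] = a - n
            for key, vals in boots.items():
                row[f"{key}_lo"] = float(np.nanquantile(vals, alpha))
                row[f"{key}_hi"] = float(np.nanquantile(vals, 1.0 - alpha))
        else:
            for key in point:
                row[f"{key}_lo"] = row[f"{key}_hi"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def gerp_burden(
    table: pd.DataFrame,
    cumulative: bool = False,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score-weighted derived-frequency burden sum_i GERP_i * f_i per
    population, the afr - nfe difference, and bootstrap CIs across sites.

    With ``cumulative`` the burden is reported at each running score
    threshold (sites with score <= threshold contribute), by default at 21
    evenly spaced thresholds over the observed range.
    """
    rng = np.random.default_rng(seed)
    scores = table.gerp.to_numpy(dtype=float)
    stats = _site_stats(table)
    contrib = {
        pop: np.where(
            np.isnan(stats[f"{pop}_dfreq"]), 0.0, stats[f"{pop}_dfreq"]
        ) * scores
        for pop in ("afr", "nfe")
    }
    if cumulative:
        if thresholds is None:
            thresholds = np.linspace(scores.min(), scores.max(), 21)
    else:
        thresholds = np.array([np.inf])
    alpha = (1.0 - ci) / 2.0
    n = scores.size
    boot_take = rng.integers(0, n, size=(n_boot, n)) if n else None
    rows = []
    for thr in np.atleast_1d(thresholds):
        mask = scores <= thr
        a = contrib["afr"][mask].sum()
        e = contrib["nfe"][mask].sum()
        row = {
            "threshold": thr, "n_sites": int(mask.sum()),
            "afr_burden": a, "nfe_burden": e, "diff_burden": a - e,
        }
        if n >= 2:
            diffs = np.empty(n_boot)
            d_site = np.where(mask, contrib["afr"] - contrib["nfe"], 0.0)
            for r in range(n_boot):
                diffs[r] = d_site[boot_take[r]].sum()
            row["diff_lo"] = float(np.quantile(diffs, alpha))
            row["diff_hi"] = float(np.quantile(diffs, 1.0 - alpha))
        else:
            row["diff_lo"] = row["diff_hi"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
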