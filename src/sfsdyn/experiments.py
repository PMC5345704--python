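"""Seeded experiment drivers producing TSV outputs.

Each experiment reproduces one of the package's canonical numerical
studies — heterozygosity responses to simple demographies, PN/PT
trajectories and sample-size dependence, selection-stratified
between-population differences with no-selection counterfactuals,
equilibrium selection rates on PN/PT, Wright-Fisher validation, and the
synthetic-exome pipeline — as deterministic tab-separated files plus a log
of the configuration hash and wall time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import demography, diffusion, pipeline, summaries, synth, wright_fisher

logger = logging.getLogger(__name__)

EXPERIMENTS = (
    "het_bottleneck",
    "het_bottleneck_growth",
    "pnpt_trajectories",
    "pnpt_vs_sample_size",
    "diff_vs_s",
    "diff_vs_time",
    "equilibrium_rates",
    "wf_validate",
    "synth_pipeline",
)

# mutation-class ratio deleterious:neutral for PN/PT
DEFAULT_CLASS_RATIO = 2.0
FIG4_S_VALUES = (6.31e-5, 6.31e-4, 0.01)


class UsageError(ValueError):
    pass


def default_s_grid(points_per_decade: int = 20) -> np.ndarray:
    """Log-spaced selection coefficients 1e-5..1e-2 including the three
    canonical weak/intermediate/strong values exactly."""
    grid = 10 ** np.arange(-5.0, -2.0 + 1e-12, 1.0 / points_per_decade)
    return np.unique(np.concatenate([grid, FIG4_S_VALUES]))


@dataclass(frozen=True)
class ExperimentSpec:
    """Configuration for one named experiment run."""

    name: str
    out_dir: str = "experiments"
    seed: int = 0
    s_grid: tuple[float, ...] = ()
    sample_sizes: tuple[int, ...] = (2, 20, 200)
    dt: float = 1e-3
    n_grid: int = 2000
    refinement: float = 3.0
    mu: float = 1.2e-8
    nonsyn_fraction: float = 2.0 / 3.0
    class_ratio: float = DEFAULT_CLASS_RATIO
    n_sites_target: int = 40_000
    n_boot: int = 500

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise UsageError(
                f"unknown experiment {self.name!r}; choose from {EXPERIMENTS}"
            )
        if any(s <= 0 for s in self.s_grid):
            raise UsageError("s grid must be positive")

    def solver_config(self, **kw) -> diffusion.SolverConfig:
        return diffusion.SolverConfig(
            dt=self.dt, n_grid=self.n_grid, refinement=self.refinement, **kw
        )

    def effective_s_grid(self) -> np.ndarray:
        return (np.asarray(self.s_grid, dtype=float) if self.s_grid
                else default_s_grid())

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _solve_to_present(
    s: float, model: demography.DemographicModel,
    cfg: diffusion.SolverConfig, theta_scale: float = 1.0,
    snapshot_gens: tuple[float, ...] = (),
) -> list[diffusion.FrequencySpectrum]:
    """Solve from the selected equilibrium at the oldest epoch's size."""
    params = diffusion.ScenarioParams.from_rates(s=s, two_N0=2.0 * model.N0)
    params = params.replace(theta=params.theta * theta_scale)
    grid = cfg.make_grid()
    rho0 = model.rho_at(model.start_gen)
    init = diffusion.equilibrium_spectrum(params, grid, rho=rho0)
    cfg = dataclasses.replace(cfg, snapshot_gens=tuple(snapshot_gens))
    return diffusion.solve(init, model, cfg)


def run_experiment(spec: ExperimentSpec) -> dict[str, Path]:
    """Dispatch an experiment; returns the mapping of output names to
    written paths and logs config hash plus wall time."""
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    logger.info("experiment %s (config %s) starting", spec.name,
                spec.config_hash())
    paths = _DISPATCH[spec.name](spec, out)
    logger.info("experiment %s finished in %.1f s", spec.name,
                time.perf_counter() - t0)
    return paths


def _traj_frame(scenario, s, S, snaps, extra=()):
    rows = []
    for snap in snaps:
        stats = {
            "heterozygosity": summaries.heterozygosity(snap),
            "derived_burden": summaries.derived_burden(snap),
            "derived_hom": summaries.derived_hom(snap),
        }
        stats.update({k: fn(snap) for k, fn in extra})
        for stat, val in stats.items():
            rows.append({
                "scenario": scenario, "s": s, "S": S,
                "time_gen": snap.time_gen, "time_coal": snap.time,
                "statistic": stat, "value": val,
            })
    return pd.DataFrame(rows)


def _het_response(spec: ExperimentSpec, out: Path, growth: bool) -> dict:
    """Heterozygosity trajectories through a bottleneck (optionally with
    exponential recovery), for post-change scaled coefficients spanning
    nearly neutral to strongly selected."""
    two_N0 = demography.TWO_N_EXPANDED
    if growth:
        model = demography.preset_bottleneck_growth(0.5, 0.0031, 920.0,
                                                    two_N0=two_N0)
        t_start, label = 920.0, "bottleneck_growth"
    else:
        model = demography.preset_bottleneck(0.13, 2000.0, two_N0=two_N0)
        t_start, label = 2000.0, "bottleneck"
    snap_gens = tuple(np.linspace(t_start, 0.0, 81))
    cfg = spec.solver_config(snapshot_gens=snap_gens)
    grid = cfg.make_grid()
    s_values = (spec.effective_s_grid() if spec.s_grid
                else np.array([1e-5, 1e-4, 6.31e-4, 2e-3, 1e-2]))
    frames = []
    for s in s_values:
        params = diffusion.ScenarioParams.from_rates(s=s, two_N0=two_N0)
        init = diffusion.equilibrium_spectrum(params, grid)
        snaps = diffusion.solve(init, model, cfg, t_start_gen=t_start)
        df = _traj_frame(label, s, params.S, snaps)
        rho_end = model.rho_at(0.0)
        df["het_equilibrium_end"] = diffusion.equilibrium_heterozygosity(
            params.S, params.theta, rho=rho_end)
        df["het_msb_asymptote"] = params.theta / params.S
        frames.append(df)
    path = out / f"het_{label}.tsv"
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return {"trajectories": path}


def _exp_het_bottleneck(spec, out):
    return _het_response(spec, out, growth=False)


def _exp_het_bottleneck_growth(spec, out):
    return _het_response(spec, out, growth=True)


def _pnpt_models():
    return {"african": demography.preset_african(),
            "ooa": demography.preset_ooa()}


def _exp_pnpt_trajectories(spec, out):
    """PN/PT through time for both population models at the canonical
    weak/intermediate/strong selection coefficients."""
    rows = []
    for pop, model in _pnpt_models().items():
        snap_gens = tuple(np.linspace(model.start_gen, 0.0, 101))
        cfg = spec.solver_config()
        s_values = spec.s_grid or FIG4_S_VALUES
        for s in s_values:
            fN = _solve_to_present(s, model, cfg, spec.class_ratio,
                                   snapshot_gens=snap_gens)
            fS = _solve_to_present(1e-12, model, cfg, 1.0,
                                   snapshot_gens=snap_gens)
            for n in spec.sample_sizes:
                for sn, ss in zip(fN, fS):
                    res = summaries.pn_pt(sn, ss, n)
                    rows.append({
                        "population": pop, "s": s, "n": n,
                        "time_gen": sn.time_gen,
                        "PN": res.PN, "PS": res.PS, "pn_pt": res.ratio,
                    })
    path = out / "pnpt_trajectories.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return {"trajectories": path}


def _exp_pnpt_vs_sample_size(spec, out):
    """Present-day PN/PT across selection coefficients and sample sizes
    for both population models."""
    rows = []
    cfg = spec.solver_config()
    s_values = spec.effective_s_grid() if spec.s_grid else np.array(
        [1e-5, 3.16e-5, 1e-4, 3.16e-4, 1e-3, 3.16e-3, 1e-2])
    for pop, model in _pnpt_models().items():
        fS = _solve_to_present(1e-12, model, cfg, 1.0)[-1]
        for s in s_values:
            fN = _solve_to_present(s, model, cfg, spec.class_ratio)[-1]
            for n in spec.sample_sizes:
                res = summaries.pn_pt(fN, fS, n)
                rows.append({"population": pop, "s": s, "n": n,
                             "pn_pt": res.ratio})
    path = out / "pnpt_vs_sample_size.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return {"table": path}


def _differences_at_present(spec: ExperimentSpec, s: float,
                            cfg: diffusion.SolverConfig) -> dict[str, dict]:
    """Present-day African-minus-OOA differences per Mb (nonsynonymous)
    under the full model and both no-selection counterfactuals."""
    afr = demography.preset_african()
    ooa = demography.preset_ooa()
    two_N0 = 2.0 * afr.N0
    params = diffusion.ScenarioParams.from_rates(s=s, two_N0=two_N0,
                                                 mu=spec.mu)
    grid = cfg.make_grid()
    init = diffusion.equilibrium_spectrum(params, grid,
                                          rho=afr.rho_at(afr.start_gen))
    split = demography.T_OOA_BOTTLENECK
    finals = {}
    pre = {
        "african": diffusion.solve(init, afr, cfg, t_end_gen=split)[-1],
        "ooa": diffusion.solve(init, ooa, cfg, t_end_gen=split)[-1],
    }
    for pop, model in (("african", afr), ("ooa", ooa)):
        finals[("full", pop)] = diffusion.solve(
            pre[pop], model, cfg, t_start_gen=split)[-1]
        for keep_mut, variant in ((True, "nosel_mut"), (False, "nosel_nomut")):
            finals[(variant, pop)] = diffusion.no_selection_counterfactual(
                pre[pop], model, cfg, keep_mutation=keep_mut,
                t_start_gen=split)[-1]
    stats = {
        "heterozygosity": summaries.heterozygosity,
        "derived_hom": summaries.derived_hom,
        "derived_burden": summaries.derived_burden,
    }
    result = {}
    for variant in ("full", "nosel_mut", "nosel_nomut"):
        result[variant] = {
            stat: summaries.per_mb_scaling(
                fn(finals[(variant, "african")])
                - fn(finals[(variant, "ooa")]),
                theta_solved=params.theta, two_N0=two_N0, mu=spec.mu,
                nonsyn_fraction=spec.nonsyn_fraction,
            )
            for stat, fn in stats.items()
        }
    return result


def _exp_diff_vs_s(spec, out):
    """African-minus-OOA differences at present vs selection coefficient,
    including the no-selection counterfactual curves."""
    cfg = spec.solver_config()
    s_values = (spec.effective_s_grid() if spec.s_grid
                else default_s_grid(points_per_decade=5))
    rows = []
    for s in s_values:
        diffs = _differences_at_present(spec, s, cfg)
        for variant, stats in diffs.items():
            for stat, val in stats.items():
                rows.append({"s": s, "variant": variant, "statistic": stat,
                             "afr_minus_ooa_per_mb": val})
    path = out / "diff_vs_s.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return {"table": path}


def _exp_diff_vs_time(spec, out):
    """Time course of the African-minus-OOA differences, relative to the
    ancestral (pre-split) level, for a grid of scaled coefficients."""
    afr = demography.preset_african()
    ooa = demography.preset_ooa()
    two_N0 = 2.0 * afr.N0
    snap_gens = tuple(np.linspace(demography.T_OOA_BOTTLENECK, 0.0, 81))
    cfg = spec.solver_config()
    s_values = (spec.effective_s_grid() if spec.s_grid
                else np.array([1e-5, 1e-4, 6.31e-4, 1e-3, 1e-2]))
    stats = {
        "heterozygosity": summaries.heterozygosity,
        "derived_hom": summaries.derived_hom,
        "derived_burden": summaries.derived_burden,
    }
    rows = []
    for s in s_values:
        params = diffusion.ScenarioParams.from_rates(s=s, two_N0=two_N0,
                                                     mu=spec.mu)
        grid = cfg.make_grid()
        init = diffusion.equilibrium_spectrum(params, grid,
                                              rho=afr.rho_at(afr.start_gen))
        split = demography.T_OOA_BOTTLENECK
        pre = diffusion.solve(init, afr, cfg, t_end_gen=split)[-1]
        anc = {stat: fn(pre) for stat, fn in stats.items()}
        cfg_snap = dataclasses.replace(cfg, snapshot_gens=snap_gens)
        tracks = {
            pop: diffusion.solve(pre, model, cfg_snap, t_start_gen=split)
            for pop, model in (("african", afr), ("ooa", ooa))
        }
        for sa, so in zip(tracks["african"], tracks["ooa"]):
            for stat, fn in stats.items():
                rows.append({
                    "s": s, "S": params.S, "time_gen": sa.time_gen,
                    "statistic": stat,
                    "afr_minus_ooa_per_mb": summaries.per_mb_scaling(
                        fn(sa) - fn(so), params.theta, two_N0, spec.mu,
                        spec.nonsyn_fraction),
                    "afr_rel_ancestral": fn(sa) - anc[stat],
                    "ooa_rel_ancestral": fn(so) - anc[stat],
                })
    path = out / "diff_vs_time.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return {"table": path}


def _exp_equilibrium_rates(spec, out):
    """Equilibrium PN/PT and the per-generation selection rate on PN/PT,
    contrasting the pre- and post-bottleneck population sizes."""
    sizes = (3801.0, 29240.0)
    cfg = spec.solver_config()
    grid = cfg.make_grid()
    l_mu = 1e-6  # arbitrary common scale; rates reported per generation
    s_values = (spec.effective_s_grid() if spec.s_grid
                else default_s_grid(points_per_decade=5))
    rows = []
    for s in s_values:
        for two_N in sizes:
            S = two_N * s
            theta_N = 2.0 * two_N * l_mu * spec.class_ratio
            theta_S = 2.0 * two_N * l_mu
            fN = diffusion.equilibrium_spectrum(
                diffusion.ScenarioParams(S=S, theta=theta_N), grid)
            fS = diffusion.equilibrium_spectrum(
                diffusion.ScenarioParams(S=0.0, theta=theta_S), grid)
            for k in list(spec.sample_sizes) + [int(two_N)]:
                PN = summaries.prob_polymorphic(fN, k)
                PS = summaries.prob_polymorphic(fS, k)
                rp = summaries.RateParams(S=S, theta_N=theta_N, k=k)
                if k == int(two_N):
                    rate = summaries.pnpt_selection_rate_population(rp, PN, PS)
                    scope = "population"
                else:
                    rate = summaries.pnpt_selection_rate_sample(rp, PN, PS)
                    scope = "sample"
                rows.append({
                    "s": s, "two_N": two_N, "k": k, "scope": scope,
                    "pn_pt": PN / (PN + PS),
                    "rate_per_2N_gen": rate,
                    "rate_per_gen": rate / two_N,
                })
    path = out / "equilibrium_rates.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return {"table": path}


def wf_validation_report(
    spec: ExperimentSpec,
    two_N_values: tuple[int, ...] = (200, 400),
    S_values: tuple[float, ...] = (0.0, 2.0, 10.0),
    bottleneck: float = 0.5,
) -> pd.DataFrame:
    """Diffusion vs expected Wright-Fisher across a bottleneck; returns the
    per-scenario comparison table."""
    frames = []
    for two_N in two_N_values:
        for S in S_values:
            s = S / two_N
            l_mu = 1.0 / (2 * two_N)  # theta = 1
            init = wright_fisher.wf_stationary_state(two_N, s, l_mu)
            n_gen = two_N // 2
            states = wright_fisher.wf_run(
                [(int(bottleneck * two_N), n_gen)], s, l_mu, init=init,
                record_every=max(1, n_gen // 5))
            gens = [st.generation for st in states]
            grid = diffusion.make_grid(spec.n_grid, spec.refinement)
            params = diffusion.ScenarioParams(S=S, theta=1.0)
            eq = diffusion.equilibrium_spectrum(params, grid)
            model = demography.preset_bottleneck(
                bottleneck, t_start=float(n_gen), two_N0=float(two_N))
            cfg = spec.solver_config(
                snapshot_gens=tuple(n_gen - g for g in gens))
            snaps = diffusion.solve(eq, model, cfg, t_start_gen=float(n_gen))
            rep = wright_fisher.compare_to_diffusion(
                states, snaps, two_N0=float(two_N))
            rep.insert(0, "two_N", two_N)
            rep.insert(1, "S", S)
            frames.append(rep)
    return pd.concat(frames, ignore_index=True)


def _exp_wf_validate(spec, out):
    rep = wf_validation_report(spec)
    path = out / "wf_validation.tsv"
    rep.to_csv(path, sep="\t", index=False)
    worst = rep.groupby(["two_N", "S", "statistic"]).rel_diff.max()
    logger.info("WF validation worst relative differences:\n%s", worst)
    return {"report": path}


def solve_present_spectra(
    spec: ExperimentSpec, s_classes: list[float]
) -> dict[float, tuple[diffusion.FrequencySpectrum,
                       diffusion.FrequencySpectrum]]:
    """Present-day (African-like, European-like) spectra for each mutation
    class; the neutral class (0.0) is solved at a tiny coefficient."""
    afr = demography.preset_african()
    ooa = demography.preset_ooa()
    cfg = spec.solver_config()
    spectra = {}
    for s in s_classes:
        s_eff = s if s > 0 else 1e-12
        fa = _solve_to_present(s_eff, afr, cfg)[-1]
        fo = _solve_to_present(s_eff, ooa, cfg)[-1]
        spectra[s] = (fa, fo)
    return spectra


def _exp_synth_pipeline(spec, out):
    """Generate a synthetic exome table from the solved population models
    and run the full binned-summary pipeline on it."""
    gc = synth.GeneratorConfig(n_sites_target=spec.n_sites_target,
                               seed=spec.seed)
    spectra = solve_present_spectra(spec, gc.class_labels())
    table = synth.generate_sites(gc, spectra)
    table_path = out / "site_table.tsv"
    synth.write_site_table(table, table_path)
    polarized = pipeline.filter_qc(pipeline.polarize(table))
    filtered, report = pipeline.filter_missing(
        polarized, gc.afr_chroms, gc.nfe_chroms)
    binning, idx = pipeline.assign_bins(filtered)
    bins = pipeline.bin_summaries(filtered, binning, idx,
                                  n_boot=spec.n_boot, seed=spec.seed)
    bins_path = out / "bin_summaries.tsv"
    bins.to_csv(bins_path, sep="\t", index=False)
    burden = pipeline.gerp_burden(filtered, cumulative=True,
                                  n_boot=spec.n_boot, seed=spec.seed)
    burden_path = out / "gerp_burden.tsv"
    burden.to_csv(burden_path, sep="\t", index=False)
    (out / "filter_report.json").write_text(json.dumps(report, indent=2))
    return {"site_table": table_path, "bin_summaries": bins_path,
            "gerp_burden": burden_path}


_DISPATCH = {
    "het_bottleneck": _exp_het_bottleneck,
    "het_bottleneck_growth": _exp_het_bottleneck_growth,
    "pnpt_trajectories": _exp_pnpt_trajectories,
    "pnpt_vs_sample_size": _exp_pnpt_vs_sample_size,
    "diff_vs_s": _exp_diff_vs_s,
    "diff_vs_time": _exp_diff_vs_time,
    "equilibrium_rates": _exp_equilibrium_rates,
    "wf_validate": _exp_wf_validate,
    "synth_pipeline": _exp_synth_pipeline,
}
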