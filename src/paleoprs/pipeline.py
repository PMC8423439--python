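"""End-to-end orchestration: filters -> harmonize -> clump -> score -> trends
-> selection test -> robustness grids, from one declarative configuration.

``run`` is a pure function of (input files, config, seed): all randomness
(null sets, down-sampling) is drawn from named sub-streams of the master
seed, and every output TSV is byte-identical across repeat runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import panels, prs, selection, sumstats, trends

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage produced an empty required output."""


@dataclass
class RunConfig:
    """Inputs, thresholds and grids for one full run."""

    ancient_prefix: str
    modern_prefix: str
    meta_path: str
    sumstats_paths: dict[str, str]          # trait name -> TSV path
    out_dir: str
    p_threshold: float = 1e-5
    miss_threshold: float = 0.96
    window_kb: float = 250.0
    use_ld_clumping: bool = False
    r2_max: float = 0.2
    p_threshold_grid: tuple = (1e-3, 1e-4, 1e-5, 1e-6)
    miss_threshold_grid: tuple = (0.96, 0.90, 0.80, 0.70)
    window_kb_grid: tuple = (250.0,)
    run_grid: bool = True
    loess_span: float = 0.75
    n_null_sets: int = 10_000
    n_downsample_reps: int = 100
    seed: int = 0
    lat_range: tuple = panels.DEFAULT_LAT_RANGE
    lon_range: tuple = panels.DEFAULT_LON_RANGE
    pseudo_haploid_periods: tuple = ("EUP", "LUP", "Mesolithic", "Neolithic", "PostNeolithic")
    force: bool = False

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff ``run`` preconditions hold."""
    problems = []
    for name in ("ancient_prefix", "modern_prefix"):
        prefix = getattr(config, name)
        for ext in (".geno", ".snp", ".ind"):
            if not os.path.exists(prefix + ext):
                problems.append(f"{name}: missing file {prefix + ext}")
    if not os.path.exists(config.meta_path):
        problems.append(f"meta_path: missing file {config.meta_path}")
    if not config.sumstats_paths:
        problems.append("sumstats_paths: at least one trait is required")
    for trait, path in config.sumstats_paths.items():
        if not os.path.exists(path):
            problems.append(f"sumstats_paths[{trait!r}]: missing file {path}")
    if not 0 < config.p_threshold <= 1:
        problems.append("p_threshold: must lie in (0, 1]")
    if not 0 < config.miss_threshold <= 1:
        problems.append("miss_threshold: must lie in (0, 1]")
    if config.window_kb <= 0:
        problems.append("window_kb: must be positive")
    for grid_name in ("p_threshold_grid", "miss_threshold_grid", "window_kb_grid"):
        if len(getattr(config, grid_name)) == 0:
            problems.append(f"{grid_name}: must be non-empty")
    if any(w <= 0 for w in config.window_kb_grid):
        problems.append("window_kb_grid: windows must be positive")
    if not 0 < config.loess_span <= 1:
        problems.append("loess_span: must lie in (0, 1]")
    if config.n_null_sets < 1:
        problems.append("n_null_sets: must be at least 1")
    if os.path.isdir(config.out_dir) and os.listdir(config.out_dir) and not config.force:
        problems.append(f"out_dir: {config.out_dir} exists and is non-empty (set force)")
    return problems


def load_cohort(config: RunConfig) -> tuple[panels.GenotypePanel, pd.DataFrame]:
    """Read, filter, period-assign and merge the ancient + modern cohort."""
    ancient = panels.read_eigenstrat(config.ancient_prefix)
    modern = panels.read_eigenstrat(config.modern_prefix)
    meta = panels.read_sample_meta(config.meta_path)
    meta = panels.assign_periods(meta)
    meta = meta[meta["period"].notna()].reset_index(drop=True)

    ancient = panels.assign_ploidy(ancient, meta, set(config.pseudo_haploid_periods))
    modern = panels.assign_ploidy(modern, meta, set(config.pseudo_haploid_periods))

    # geographic box applies to the carbon-dated samples; modern references
    # are pre-selected Europeans and carry no excavation coordinates
    ancient_meta = meta[meta["period"] != "Modern"]
    modern_meta = meta[meta["period"] == "Modern"]
    ancient_meta = panels.filter_geobox(ancient_meta, config.lat_range, config.lon_range)
    meta = pd.concat([ancient_meta, modern_meta], ignore_index=True)

    ancient = panels.filter_samples_missingness(ancient, config.miss_threshold)
    merged = panels.intersect_variants(ancient, modern)
    if merged.n_variants == 0:
        raise PipelineError("variant intersection produced an empty panel")
    merged, meta = panels.restrict_to_meta(merged, meta)
    if merged.n_samples == 0:
        raise PipelineError("cohort filters removed every sample")
    merged.validate()
    return merged, meta


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle to ``out_dir``.

    Outputs per trait: scores_<trait>.tsv and loess_<trait>.tsv; shared:
    trends.tsv, group_tests.tsv, downsample.tsv, selection.tsv, grid.tsv,
    run.log, config.json. Returns the in-memory tables keyed by name.
    """
    problems = validate_config(config)
    if problems:
        raise PipelineError("invalid configuration: " + "; ".join(problems))
    os.makedirs(config.out_dir, exist_ok=True)

    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("paleoprs")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_stages(config)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig) -> dict:
    seed_seq = np.random.SeedSequence(config.seed)
    seed_selection, seed_downsample = (int(s) for s in seed_seq.generate_state(2) % (2**31))

    panel, meta = load_cohort(config)
    logger.info("cohort: %d samples x %d variants after filters", panel.n_samples, panel.n_variants)

    tables = {}
    for trait, path in config.sumstats_paths.items():
        table = sumstats.read_sumstats(path)
        table = sumstats.drop_ambiguous(sumstats.filter_biallelic(table))
        table = sumstats.align_effect_alleles(table, panel)
        tables[trait] = table
        if len(table) == 0:
            raise PipelineError(f"trait {trait!r}: no variants remain after harmonization")

    out: dict = {"panel": panel, "meta": meta}
    ages = meta["age_bp"].to_numpy(dtype=float)
    periods_arr = meta["period"].to_numpy()

    trend_rows, group_rows, downsample_rows = [], [], []
    trait_leads: dict[str, np.ndarray] = {}
    for trait, table in tables.items():
        selected = sumstats.select_by_pvalue(table, config.p_threshold)
        if len(selected) == 0:
            logger.warning("trait %s: no QTLs below p < %g; skipped", trait, config.p_threshold)
            continue
        leads = (prs.clump_ld(selected, panel, config.window_kb, config.r2_max)
                 if config.use_ld_clumping else prs.clump_window(selected, config.window_kb))
        scored = prs.scale_scores(prs.score_samples(panel, leads))
        trait_leads[trait] = leads.leads["panel_index"].to_numpy(dtype=int)

        scores_tsv = scored.merge(meta[["sample_id", "age_bp", "period"]], on="sample_id")
        scores_tsv = scores_tsv[["sample_id", "age_bp", "period", "raw_score",
                                 "scaled_score", "n_variants", "n_imputed"]]
        scores_tsv.to_csv(os.path.join(config.out_dir, f"scores_{trait}.tsv"),
                          sep="\t", index=False, float_format="%.10g")
        out[f"scores_{trait}"] = scores_tsv

        scaled = scored["scaled_score"].to_numpy()
        fit = trends.piecewise_fit(scaled, ages, periods_arr)
        for side, res in fit.items():
            trend_rows.append({"trait": trait, "side": side, "n": res.n, "r": res.r,
                               "p": res.p, "signed_neglog10_p": res.signed_neglog10_p,
                               "slope": res.slope, "intercept": res.intercept})
        if len(scaled) > 10:
            grid_ages, fitted = trends.loess_curve(scaled, ages, span=config.loess_span)
            pd.DataFrame({"age_bp": grid_ages, "loess_fit": fitted}).to_csv(
                os.path.join(config.out_dir, f"loess_{trait}.tsv"), sep="\t",
                index=False, float_format="%.10g")
        comparisons, anova = trends.adjacent_period_tests(scaled, periods_arr)
        for c in comparisons:
            group_rows.append({"trait": trait, "period_a": c.period_a, "period_b": c.period_b,
                               "t": c.t, "p": c.p, "mean_a": c.mean_a, "mean_b": c.mean_b,
                               "n_a": c.n_a, "n_b": c.n_b, "degenerate": c.degenerate,
                               "anova_F": anova[0], "anova_p": anova[1]})
        try:
            ds = trends.downsample_consistency(scaled, ages, periods_arr,
                                               n_reps=config.n_downsample_reps,
                                               seed=seed_downsample)
            downsample_rows.append({"trait": trait, "full_r": ds["full_r"],
                                    "mean_r": ds["mean"], "sd_r": ds["sd"],
                                    "sign_agreement": ds["sign_agreement"],
                                    "n_pre": ds["n_pre"], "n_post": ds["n_post"]})
        except ValueError as err:
            logger.warning("trait %s: down-sampling skipped (%s)", trait, err)

    if not trait_leads:
        raise PipelineError("no trait produced a scorable variant set")

    for name, rows in (("trends", trend_rows), ("group_tests", group_rows),
                       ("downsample", downsample_rows)):
        frame = pd.DataFrame(rows)
        frame.to_csv(os.path.join(config.out_dir, f"{name}.tsv"), sep="\t",
                     index=False, float_format="%.10g")
        out[name] = frame

    results = selection.selection_scan(panel, meta, trait_leads,
                                       n_sets=config.n_null_sets, seed=seed_selection)
    sel_frame = selection.selection_results_frame(results)
    sel_frame.to_csv(os.path.join(config.out_dir, "selection.tsv"), sep="\t",
                     index=False, float_format="%.10g")
    out["selection"] = sel_frame

    if config.run_grid:
        grid = prs.threshold_grid(panel, meta, tables, config.p_threshold_grid,
                                  config.miss_threshold_grid, config.window_kb_grid,
                                  use_ld=config.use_ld_clumping, r2_max=config.r2_max)
        grid.to_csv(os.path.join(config.out_dir, "grid.tsv"), sep="\t",
                    index=False, float_format="%.10g")
        out["grid"] = grid

    with open(os.path.join(config.out_dir, "config.json"), "w") as fh:
        fh.write(config.to_json() + "\n")
    return out
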