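"""Polygenic scores on sparse pseudo-haploid panels.

The score of sample *i* is the weighted dosage sum ``S_i = sum_n X_in b_n``
over the *m* clumped lead variants, where a missing dosage is substituted
with that variant's mean genotyped dosage over the entire merged panel, so
imputation pulls a sample toward the cohort average rather than skewing the
score in either direction. Scores are min-max scaled to [-1, 1] per trait
over all samples jointly before any temporal analysis.

Lead variants come from greedy p-value clumping: repeatedly take the most
significant remaining record and discard its neighbors, either every variant
within a physical window (``clump_window``) or only those in linkage
disequilibrium r^2 above a cutoff with the lead (``clump_ld``, r^2 measured
on the modern diploid samples, whose calls preserve heterozygotes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import DIPLOID, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class ClumpResult:
    """Ordered lead variants retained by clumping."""

    leads: pd.DataFrame  # rows of the input table, selection order
    window_kb: float
    r2_max: float | None = None

    def __len__(self) -> int:
        return len(self.leads)


def _clump_order(table: pd.DataFrame) -> pd.DataFrame:
    # deterministic tie-break: p, then (chrom, pos)
    return table.sort_values(["pvalue", "chrom", "pos"], kind="mergesort").reset_index(drop=True)


def clump_window(table: pd.DataFrame, window_kb: float = 250.0) -> ClumpResult:
    """Greedy physical-window clumping.

    Starting at the most significant variant, all variants on the same
    chromosome within ``window_kb`` kilobases (inclusive, |pos - lead_pos|
    <= window) are excluded, and the loop repeats until no variants remain.
    Output is independent of input row order.
    """
    srt = _clump_order(table)
    chrom = srt["chrom"].to_numpy()
    pos = srt["pos"].to_numpy(dtype=float)
    window = float(window_kb) * 1000.0
    alive = np.ones(len(srt), dtype=bool)
    lead_rows: list[int] = []
    for i in range(len(srt)):
        if not alive[i]:
            continue
        lead_rows.append(i)
        hit = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        alive[hit] = False
    return ClumpResult(srt.iloc[lead_rows].reset_index(drop=True), window_kb=float(window_kb))


def clump_ld(
    table: pd.DataFrame,
    panel: GenotypePanel,
    window_kb: float = 250.0,
    r2_max: float = 0.2,
) -> ClumpResult:
    """Greedy LD clumping: discard only in-window variants with r^2 > ``r2_max``.

    r^2 is the squared Pearson correlation of dosages over pairwise-complete
    calls of the panel's modern *diploid* samples (pseudo-haploid calls
    distort pairwise correlation). A pair with fewer than two complete
    observations has unknown LD and is retained (logged).

    ``table`` must carry a ``panel_index`` column (from
    :func:`paleoprs.sumstats.align_effect_alleles`).
    """
    if "panel_index" not in table.columns:
        raise ValueError("clump_ld needs a panel_index column; align the table first")
    srt = _clump_order(table)
    chrom = srt["chrom"].to_numpy()
    pos = srt["pos"].to_numpy(dtype=float)
    pidx = srt["panel_index"].to_numpy(dtype=int)
    window = float(window_kb) * 1000.0

    dip = np.asarray(panel.ploidy) == DIPLOID
    D = panel.dosage[dip]
    n_unknown = 0

    alive = np.ones(len(srt), dtype=bool)
    lead_rows: list[int] = []
    for i in range(len(srt)):
        if not alive[i]:
            continue
        lead_rows.append(i)
        alive[i] = False
        cand = np.flatnonzero(alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window))
        if cand.size == 0:
            continue
        r2 = _pairwise_r2(D[:, pidx[i]], D[:, pidx[cand]])
        unknown = np.isnan(r2)
        n_unknown += int(unknown.sum())
        alive[cand[(~unknown) & (r2 > r2_max)]] = False
    if n_unknown:
        logger.info("clump_ld: %d candidate pairs had <2 complete observations; retained", n_unknown)
    return ClumpResult(srt.iloc[lead_rows].reset_index(drop=True),
                       window_kb=float(window_kb), r2_max=float(r2_max))


def _pairwise_r2(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of ``x`` against each column of ``Y`` over
    pairwise-complete observations; NaN when undefined (<2 complete pairs or
    zero variance)."""
    x = x[:, None]
    complete = ~np.isnan(x) & ~np.isnan(Y)
    n = complete.sum(axis=0).astype(float)
    xs = np.where(complete, x, 0.0)
    ys = np.where(complete, Y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xs.sum(axis=0) / n
        my = ys.sum(axis=0) / n
        sxy = (xs * ys).sum(axis=0) - n * mx * my
        sxx = (xs * xs).sum(axis=0) - n * mx * mx
        syy = (ys * ys).sum(axis=0) - n * my * my
        r2 = (sxy * sxy) / (sxx * syy)
    r2[n < 2] = np.nan
    return r2


def mean_dosage(panel: GenotypePanel) -> np.ndarray:
    """Per-variant mean genotyped dosage over the entire panel (NaN-skipping;
    NaN for a variant with zero genotyped calls)."""
    with np.errstate(invalid="ignore"):
        all_missing = np.isnan(panel.dosage).all(axis=0)
        out = np.full(panel.n_variants, np.nan)
        if (~all_missing).any():
            out[~all_missing] = np.nanmean(panel.dosage[:, ~all_missing], axis=0)
    return out


def score_samples(panel: GenotypePanel, leads: ClumpResult | pd.DataFrame) -> pd.DataFrame:
    """Raw polygenic scores ``S = sum_n X_n beta_n`` with mean-dosage imputation.

    Returns a DataFrame with columns ``sample_id, raw_score, n_variants,
    n_imputed``. Lead variants with zero genotyped calls are excluded from
    scoring (logged); a fully missing sample receives the population-average
    score ``sum_n mean_dosage_n * beta_n``.
    """
    table = leads.leads if isinstance(leads, ClumpResult) else leads
    if "panel_index" not in table.columns:
        raise ValueError("score_samples needs a panel_index column; align the table first")
    idx = table["panel_index"].to_numpy(dtype=int)
    beta = table["beta"].to_numpy(dtype=float)

    means = mean_dosage(panel)[idx]
    usable = ~np.isnan(means)
    if (~usable).any():
        logger.info("score_samples: excluded %d lead variants with zero genotyped calls",
                    int((~usable).sum()))
    idx, beta, means = idx[usable], beta[usable], means[usable]

    X = panel.dosage[:, idx]
    missing = np.isnan(X)
    X = np.where(missing, means[None, :], X)
    raw = X @ beta
    return pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "raw_score": raw,
            "n_variants": len(idx),
            "n_imputed": missing.sum(axis=1),
        }
    )


def scale_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale raw scores to [-1, 1] over all samples of the trait.

    The minimum maps to -1 and the maximum to +1; if every score is equal
    (degenerate range) all scaled values are set to 0.
    """
    raw = scores["raw_score"].to_numpy(dtype=float)
    out = scores.copy()
    if len(raw) == 0:
        out["scaled_score"] = raw
        return out
    lo, hi = np.min(raw), np.max(raw)
    if hi == lo:
        out["scaled_score"] = np.zeros_like(raw)
    else:
        out["scaled_score"] = 2.0 * (raw - lo) / (hi - lo) - 1.0
    return out


def threshold_grid(
    panel: GenotypePanel,
    meta: pd.DataFrame,
    tables: dict[str, pd.DataFrame],
    p_thresholds,
    miss_thresholds,
    window_kbs,
    use_ld: bool = False,
    r2_max: float = 0.2,
) -> pd.DataFrame:
    """Robustness sweep over p-value x sample-missingness x window grids.

    For every combination and trait the full chain is recomputed — sample
    refilter, p selection, clumping, scoring, scaling, pre/post-Neolithic
    piecewise fit — and one row per epoch side is emitted with the signed
    -log10 p used for trend-consistency heatmaps. Mean dosages for
    imputation are recomputed on each cell's refiltered panel.
    Combinations yielding fewer than 3 samples or no variants are marked NA.
    """
    from .sumstats import select_by_pvalue
    from .trends import piecewise_fit

    rows = []
    for miss_t in miss_thresholds:
        from .panels import filter_samples_missingness, restrict_to_meta

        sub_panel = filter_samples_missingness(panel, miss_t)
        sub_panel, sub_meta = restrict_to_meta(sub_panel, meta)
        for trait, table in tables.items():
            for p_t in p_thresholds:
                selected = select_by_pvalue(table, p_t)
                for w in window_kbs:
                    cell = dict(trait=trait, p_threshold=p_t, miss_threshold=miss_t,
                                window_kb=w)
                    if len(selected) == 0 or sub_panel.n_samples < 3:
                        logger.info("grid cell %s: NA (insufficient data)", cell)
                        for side in ("pre", "post"):
                            rows.append({**cell, "epoch_side": side, "n": 0,
                                         "r": np.nan, "p": np.nan,
                                         "signed_neglog10_p": np.nan})
                        continue
                    leads = (clump_ld(selected, sub_panel, w, r2_max) if use_ld
                             else clump_window(selected, w))
                    scored = scale_scores(score_samples(sub_panel, leads))
                    fit = piecewise_fit(
                        scored["scaled_score"].to_numpy(),
                        sub_meta["age_bp"].to_numpy(dtype=float),
                        sub_meta["period"].to_numpy(),
                    )
                    for side, res in fit.items():
                        rows.append({**cell, "epoch_side": side, "n": res.n,
                                     "r": res.r, "p": res.p,
                                     "signed_neglog10_p": res.signed_neglog10_p})
    return pd.DataFrame(rows)
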