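"""Temporal trends of polygenic scores against carbon-dated sample age.

The age axis is years BP, so larger ages are older samples: a trait whose
score *increases toward the present* shows a *negative* Pearson correlation
with age. Trend strength is summarized as ``sign(r) * (-log10 p)``, the
signed log p-value plotted in the robustness heatmaps.

The piecewise model splits samples at the Neolithic transition — EUP, LUP
and Mesolithic samples on the "pre" side; Neolithic, post-Neolithic and
modern (age 0) samples on the "post" side — and fits an independent
ordinary least-squares line per side. LOESS curves (local quadratic fits
with tri-cube weights) visualize the trajectory without a fixed breakpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .periods import PERIOD_ORDER, POST_NEOLITHIC, PRE_NEOLITHIC

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny  # p-value floor so -log10 p stays finite


@dataclass
class TrendResult:
    """Correlation and OLS summary of score against age for one sample group."""

    n: int
    r: float = np.nan
    p: float = np.nan
    signed_neglog10_p: float = np.nan
    slope: float = np.nan
    intercept: float = np.nan
    slope_se: float = np.nan

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.r)


@dataclass
class GroupComparison:
    """Student's t comparison of mean scores between two adjacent periods."""

    period_a: str
    period_b: str
    t: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    degenerate: bool = False  # zero pooled variance with unequal means


def signed_neglog10(r: float, p: float) -> float:
    """``sign(r) * (-log10 p)``; p is floored at the smallest positive float."""
    if not np.isfinite(r) or not np.isfinite(p):
        return np.nan
    return float(np.sign(r) * (-np.log10(max(p, _TINY))))


def pearson_age_correlation(scores: np.ndarray, ages: np.ndarray) -> TrendResult:
    """Pearson correlation of score with age, two-sided p from the t transform
    with n-2 degrees of freedom, plus the OLS line."""
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = len(scores)
    if n < 3:
        logger.warning("pearson_age_correlation: n=%d < 3; returning NA", n)
        return TrendResult(n=n)
    if np.ptp(scores) == 0 or np.ptp(ages) == 0:
        logger.warning("pearson_age_correlation: zero variance; returning NA")
        return TrendResult(n=n)
    fit = stats.linregress(ages, scores)
    r, p = float(fit.rvalue), float(fit.pvalue)
    return TrendResult(
        n=n, r=r, p=p, signed_neglog10_p=signed_neglog10(r, p),
        slope=float(fit.slope), intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
    )


def piecewise_fit(
    scores: np.ndarray,
    ages: np.ndarray,
    periods: np.ndarray,
    pre_periods=PRE_NEOLITHIC,
    post_periods=POST_NEOLITHIC,
) -> dict[str, TrendResult]:
    """Independent score-on-age OLS fits before and after the Neolithic
    transition; a side with fewer than 3 samples is reported NA."""
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    periods = np.asarray(periods, dtype=object)
    out = {}
    for side, members in (("pre", pre_periods), ("post", post_periods)):
        mask = np.isin(periods, list(members))
        if mask.sum() < 3:
            logger.warning("piecewise_fit: %s-Neolithic side has n=%d < 3; NA",
                           side, int(mask.sum()))
            out[side] = TrendResult(n=int(mask.sum()))
        else:
            out[side] = pearson_age_correlation(scores[mask], ages[mask])
    return out


def loess_curve(
    scores: np.ndarray,
    ages: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    n_grid: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """LOESS: local polynomial regression with tri-cube weights.

    At each of ``n_grid`` uniformly spaced ages, a degree-``degree``
    polynomial is fit by weighted least squares to the ``span`` fraction of
    nearest samples, with tri-cube weights ``(1 - (d/dmax)^3)^3``. Returns
    ``(grid_ages, fitted)``.
    """
    if not 0 < span <= 1:
        raise ValueError("LOESS span must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = len(scores)
    if n <= 10:
        raise ValueError("LOESS needs more than 10 samples")
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)
    grid = np.linspace(ages.min(), ages.max(), n_grid)
    fitted = np.empty(n_grid)
    for j, x0 in enumerate(grid):
        d = np.abs(ages - x0)
        sel = np.argpartition(d, k - 1)[:k]
        dmax = d[sel].max()
        if dmax == 0:
            w = np.ones(k)
        else:
            w = np.clip(1 - (d[sel] / dmax) ** 3, 0, None) ** 3
            if not w.any():
                w = np.ones(k)
        deg = degree
        # need more positively weighted points than coefficients
        while deg > 0 and (w > 0).sum() < deg + 1:
            deg -= 1
        coeffs = np.polynomial.polynomial.polyfit(
            ages[sel] - x0, scores[sel], deg, w=np.sqrt(w)
        )
        fitted[j] = coeffs[0]
    return grid, fitted


def adjacent_period_tests(
    scores: np.ndarray, periods: np.ndarray, min_n: int = 2
) -> tuple[list[GroupComparison], tuple[float, float]]:
    """Student's (pooled-variance) t-tests between chronologically adjacent
    periods, plus a one-way ANOVA across all represented periods.

    Groups with fewer than ``min_n`` samples are skipped (logged). Returns
    ``(comparisons, (anova_F, anova_p))``. A pair of constant groups with
    unequal means has zero pooled variance; it is reported with ``p = 0``
    (the limit) and flagged ``degenerate``.
    """
    scores = np.asarray(scores, dtype=float)
    periods = np.asarray(periods, dtype=object)
    groups = {p: scores[periods == p] for p in PERIOD_ORDER if (periods == p).sum() > 0}
    usable = [p for p, v in groups.items() if len(v) >= min_n]
    skipped = [p for p in groups if p not in usable]
    if skipped:
        logger.info("adjacent_period_tests: skipped periods with n<%d: %s", min_n, skipped)

    comparisons = []
    for a, b in zip(usable[:-1], usable[1:]):
        va, vb = groups[a], groups[b]
        pooled_var = (np.var(va, ddof=1) * (len(va) - 1) + np.var(vb, ddof=1) * (len(vb) - 1))
        if pooled_var == 0:
            if np.mean(va) == np.mean(vb):
                t, p, degen = 0.0, 1.0, False
            else:
                t = np.inf * np.sign(np.mean(va) - np.mean(vb))
                p, degen = 0.0, True
        else:
            t, p = stats.ttest_ind(va, vb, equal_var=True)
            t, p, degen = float(t), float(p), False
        comparisons.append(GroupComparison(a, b, t, p, float(np.mean(va)),
                                           float(np.mean(vb)), len(va), len(vb), degen))

    if len(usable) >= 2:
        arrays = [groups[p] for p in usable]
        if np.ptp(np.concatenate(arrays)) == 0:
            anova = (np.nan, np.nan)  # all scores identical: F undefined
        else:
            f, p = stats.f_oneway(*arrays)
            anova = (float(f), float(p))
    else:
        anova = (np.nan, np.nan)
    return comparisons, anova


def downsample_consistency(
    scores: np.ndarray,
    ages: np.ndarray,
    periods: np.ndarray,
    n_reps: int = 100,
    seed: int = 0,
    post_periods=POST_NEOLITHIC,
    pre_periods=PRE_NEOLITHIC,
) -> dict:
    """Down-sample the post-Neolithic side to the pre-Neolithic sample size
    and recompute the post-side score-age correlation ``n_reps`` times.

    Returns the full-data post-side r, the replicate r values, their mean and
    sd, and the fraction of replicates whose r sign agrees with the full-data
    sign — the robustness check that observed trends do not hinge on the
    post-Neolithic sample-size excess.
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    periods = np.asarray(periods, dtype=object)
    post_idx = np.flatnonzero(np.isin(periods, list(post_periods)))
    n_pre = int(np.isin(periods, list(pre_periods)).sum())
    if not (len(post_idx) >= n_pre >= 3):
        raise ValueError(
            f"need n_post ({len(post_idx)}) >= n_pre ({n_pre}) >= 3 for down-sampling"
        )
    full = pearson_age_correlation(scores[post_idx], ages[post_idx])
    rng = np.random.default_rng(seed)
    rep_r = np.empty(n_reps)
    for i in range(n_reps):
        take = rng.choice(post_idx, size=n_pre, replace=False)
        rep_r[i] = pearson_age_correlation(scores[take], ages[take]).r
    finite = rep_r[np.isfinite(rep_r)]
    sign_agreement = float(np.mean(np.sign(finite) == np.sign(full.r))) if finite.size else np.nan
    return {
        "full_r": full.r,
        "rep_r": rep_r,
        "mean": float(np.mean(finite)) if finite.size else np.nan,
        "sd": float(np.std(finite, ddof=1)) if finite.size > 1 else np.nan,
        "sign_agreement": sign_agreement,
        "n_pre": n_pre,
        "n_post": len(post_idx),
    }
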