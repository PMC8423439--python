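"""Selection test: trait Fst against an LD/MAF-matched resampling null.

A trend in polygenic score over time can reflect directional selection on the
trait's alleles or plain genetic drift. The test asks whether the mean
allele-frequency differentiation (Fst) of a trait's lead SNPs between two
adjacent time periods exceeds what matched random SNP sets show: the null
distribution is built from 10,000 sets of background variants matched to the
trait SNPs on minor allele frequency (bins of width 0.05) and LD score
(quintiles of the sum of r^2 to variants within 1 Mb, measured on the modern
diploid samples), each set of equal size, scored with the same mean-Fst
statistic, and compared two-tailed with an add-one empirical p-value.

Fst uses the Hudson estimator with its finite-sample correction, which is
robust to unequal and small chromosome counts — the norm for pseudo-haploid
ancient data, where each call observes a single chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import DIPLOID, PSEUDO_HAPLOID, GenotypePanel
from .periods import PERIOD_ORDER

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    trait: str
    period_a: str
    period_b: str
    n_snps: int
    mean_fst: float
    null_mean: float
    null_sd: float
    p_empirical: float
    p_bonferroni: float = np.nan
    null_draws: np.ndarray | None = None


def group_allele_freq(panel: GenotypePanel, sample_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Allele-1 frequency and chromosome count per variant within a sample group.

    A pseudo-haploid call observes exactly one chromosome (dosage 2 counts as
    one allele copy on one chromosome); a diploid call contributes two
    chromosomes; missing calls contribute nothing. Frequency is NaN where the
    chromosome count is zero.
    """
    sample_mask = np.asarray(sample_mask)
    if sample_mask.dtype == bool:
        sample_mask = np.flatnonzero(sample_mask)
    if sample_mask.size == 0:
        raise ValueError("group_allele_freq: empty sample group")
    D = panel.dosage[sample_mask]
    ph = (np.asarray(panel.ploidy)[sample_mask] == PSEUDO_HAPLOID)[:, None]
    observed = ~np.isnan(D)
    copies = np.where(ph, np.nan_to_num(D) / 2.0, np.nan_to_num(D))
    chroms = np.where(ph, 1.0, 2.0) * observed
    n = chroms.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, (copies * observed).sum(axis=0) / n, np.nan)
    return p, n


def hudson_fst(p1, n1, p2, n2) -> np.ndarray | float:
    """Hudson Fst with sample-size correction (vectorized).

    numerator = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)

    NaN where either chromosome count is < 2 or the denominator is 0.
    Symmetric in the two populations; approaches 1 for a fixed difference.
    """
    p1, n1, p2, n2 = (np.asarray(a, dtype=float) for a in (p1, n1, p2, n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num / den
    fst = np.where((n1 < 2) | (n2 < 2) | (den == 0), np.nan, fst)
    return fst if fst.ndim else float(fst)


def per_variant_fst(
    panel: GenotypePanel, mask_a: np.ndarray, mask_b: np.ndarray
) -> np.ndarray:
    """Hudson Fst between two sample groups for every variant (NaN = unusable)."""
    p1, n1 = group_allele_freq(panel, mask_a)
    p2, n2 = group_allele_freq(panel, mask_b)
    return hudson_fst(p1, n1, p2, n2)


def mean_trait_fst(fst: np.ndarray, trait_idx: np.ndarray, method: str = "mean") -> tuple[float, int]:
    """Mean Fst over the trait's usable SNPs.

    ``method="mean"`` (default) is the plain average of per-SNP Fst values;
    SNPs with undefined Fst are excluded. Returns ``(mean, n_usable)``.
    """
    if method != "mean":
        raise ValueError("per-SNP values support only method='mean'; "
                         "use mean_trait_fst_components for ratio-of-averages")
    vals = np.asarray(fst, dtype=float)[np.asarray(trait_idx, dtype=int)]
    usable = np.isfinite(vals)
    if not usable.any():
        logger.warning("mean_trait_fst: no usable SNPs for this comparison")
        return np.nan, 0
    return float(vals[usable].mean()), int(usable.sum())


def mean_trait_fst_components(
    panel: GenotypePanel, trait_idx: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray
) -> float:
    """Ratio-of-averages alternative: sum of Hudson numerators over sum of
    denominators across the trait SNPs."""
    p1, n1 = group_allele_freq(panel, mask_a)
    p2, n2 = group_allele_freq(panel, mask_b)
    idx = np.asarray(trait_idx, dtype=int)
    p1, n1, p2, n2 = p1[idx], n1[idx], p2[idx], n2[idx]
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok &= np.isfinite(num) & (den > 0)
    if not ok.any():
        return np.nan
    return float(num[ok].sum() / den[ok].sum())


# ---------------------------------------------------------------------------
# LD scores and the matched null
# ---------------------------------------------------------------------------

def ld_scores(panel: GenotypePanel, window_bp: float = 1_000_000.0) -> np.ndarray:
    """Per-variant LD score: sum of r^2 to other variants within ``window_bp``,
    computed on the modern diploid samples (pairwise-complete; undefined pairs
    contribute 0)."""
    dip = np.asarray(panel.ploidy) == DIPLOID
    D = panel.dosage[dip]
    out = np.zeros(panel.n_variants)
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy(dtype=float)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size < 2:
            continue
        sub = D[:, idx]
        if np.isnan(sub).any():
            r = np.ma.corrcoef(np.ma.masked_invalid(sub), rowvar=False)
            r2 = np.asarray(r.filled(0.0)) ** 2
        else:
            with np.errstate(invalid="ignore"):
                r2 = np.corrcoef(sub, rowvar=False) ** 2
            r2 = np.nan_to_num(r2)
        near = np.abs(pos[idx][:, None] - pos[idx][None, :]) <= window_bp
        np.fill_diagonal(near, False)
        out[idx] = (r2 * near).sum(axis=1)
    return out


def _maf_bins(panel: GenotypePanel, width: float) -> np.ndarray:
    p, _ = group_allele_freq(panel, np.arange(panel.n_samples))
    maf = np.minimum(p, 1 - p)
    with np.errstate(invalid="ignore"):
        bins = np.floor(maf / width).astype(float)
    n_bins = int(np.ceil(0.5 / width))
    bins = np.clip(bins, 0, n_bins - 1)
    bins[~np.isfinite(maf)] = -1
    return bins.astype(int)


def _ld_quantile_labels(ld: np.ndarray, n_quantiles: int) -> np.ndarray:
    qs = np.quantile(ld, np.linspace(0, 1, n_quantiles + 1)[1:-1])
    return np.searchsorted(qs, ld, side="right")


def build_matched_null(
    panel: GenotypePanel,
    trait_idx: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    n_sets: int = 10_000,
    seed: int = 0,
    maf_bin_width: float = 0.05,
    n_ld_quantiles: int = 5,
    ld_window_bp: float = 1_000_000.0,
    fst: np.ndarray | None = None,
    ld: np.ndarray | None = None,
) -> np.ndarray:
    """Null distribution of mean Fst from MAF- and LD-matched background sets.

    Every panel variant is binned by panel-wide MAF (bins of ``maf_bin_width``)
    and LD-score quantile. Each of the ``n_sets`` null sets draws, for every
    usable trait SNP, one background variant uniformly from the same
    (MAF bin, LD stratum) cell, without replacement within the set, and takes
    the mean per-SNP Fst exactly as the observed statistic does. A cell with
    no background variant falls back to the nearest non-empty MAF bin within
    the same LD stratum (logged), then to any stratum.

    Precomputed ``fst``/``ld`` arrays may be passed to amortize repeated calls.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    trait_idx = np.asarray(trait_idx, dtype=int)
    if fst is None:
        fst = per_variant_fst(panel, mask_a, mask_b)
    usable = np.isfinite(fst)
    trait_usable = trait_idx[usable[trait_idx]]
    k_total = trait_usable.size
    if k_total == 0:
        raise ValueError("build_matched_null: no usable trait SNPs")

    maf_bin = _maf_bins(panel, maf_bin_width)
    if ld is None:
        ld = ld_scores(panel, ld_window_bp)
    ld_q = _ld_quantile_labels(ld, n_ld_quantiles)

    in_trait = np.zeros(panel.n_variants, dtype=bool)
    in_trait[trait_idx] = True
    background = usable & ~in_trait & (maf_bin >= 0)

    # background index lists per (maf_bin, ld_stratum) cell
    cells: dict[tuple[int, int], np.ndarray] = {}
    bg_idx = np.flatnonzero(background)
    for key in set(zip(maf_bin[bg_idx], ld_q[bg_idx])):
        sel = bg_idx[(maf_bin[bg_idx] == key[0]) & (ld_q[bg_idx] == key[1])]
        cells[key] = sel

    def resolve_cell(m: int, q: int) -> tuple[int, int]:
        if (m, q) in cells:
            return (m, q)
        same_q = sorted((key for key in cells if key[1] == q), key=lambda k: (abs(k[0] - m), k[0]))
        if same_q:
            logger.info("matched null: empty cell (maf_bin=%d, ld_q=%d); using maf_bin=%d",
                        m, q, same_q[0][0])
            return same_q[0]
        anywhere = sorted(cells, key=lambda k: (abs(k[0] - m), abs(k[1] - q), k))
        logger.info("matched null: empty LD stratum %d; falling back to cell %s", q, anywhere[0])
        return anywhere[0]

    # group trait SNPs by resolved cell
    demand: dict[tuple[int, int], int] = {}
    for v in trait_usable:
        key = resolve_cell(int(maf_bin[v]), int(ld_q[v]))
        demand[key] = demand.get(key, 0) + 1

    totals = np.zeros(n_sets)
    for key in sorted(demand):
        k = demand[key]
        pool = cells[key]
        # widen the pool with nearest MAF bins until it can cover k distinct draws
        m, q = key
        delta = 1
        while pool.size < k:
            for mm in (m - delta, m + delta):
                if (mm, q) in cells:
                    pool = np.concatenate([pool, cells[(mm, q)]])
            delta += 1
            if delta > 2 * len(cells) + 2:
                raise ValueError("matched null: background too small for the trait set")
        pool_fst = fst[pool]
        chunk = max(1, min(n_sets, int(4e6 // max(pool.size, 1))))
        start = 0
        while start < n_sets:
            stop = min(start + chunk, n_sets)
            u = rng.random((stop - start, pool.size))
            take = np.argpartition(u, k - 1, axis=1)[:, :k]
            totals[start:stop] += pool_fst[take].sum(axis=1)
            start = stop
    return totals / k_total


def empirical_two_tailed_p(observed: float, null_draws: np.ndarray) -> float:
    """Add-one two-tailed empirical p:
    ``min(1, 2 * min[(1+#{null>=obs})/(N+1), (1+#{null<=obs})/(N+1)])``."""
    null_draws = np.asarray(null_draws, dtype=float)
    n = null_draws.size
    if n < 1:
        raise ValueError("empirical p needs at least one null draw")
    upper = (1 + np.sum(null_draws >= observed)) / (n + 1)
    lower = (1 + np.sum(null_draws <= observed)) / (n + 1)
    return float(min(1.0, 2.0 * min(upper, lower)))


def bonferroni_adjust(p_values, k: int | None = None) -> np.ndarray:
    """Bonferroni correction over the whole family of tests, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    k = p.size if k is None else k
    return np.minimum(1.0, p * k)


def selection_scan(
    panel: GenotypePanel,
    meta: pd.DataFrame,
    trait_leads: dict[str, np.ndarray],
    n_sets: int = 10_000,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
    min_group: int = 2,
    keep_null: bool = False,
    **null_kwargs,
) -> list[SelectionResult]:
    """Run the full selection test for every trait x adjacent-period pair.

    ``trait_leads`` maps trait name -> panel variant indices of its clumped
    lead SNPs. ``pairs`` defaults to chronologically adjacent period pairs
    present in the metadata with at least ``min_group`` samples each.
    Bonferroni correction spans all tests actually performed (family size =
    number of result rows). Null-set seeds derive deterministically from
    ``seed``.
    """
    periods = meta.set_index("sample_id").loc[panel.sample_ids, "period"].to_numpy()
    present = [p for p in PERIOD_ORDER
               if (pd.Series(periods) == p).sum() >= min_group]
    if pairs is None:
        pairs = list(zip(present[:-1], present[1:]))

    ld = ld_scores(panel, null_kwargs.get("ld_window_bp", 1_000_000.0))
    results: list[SelectionResult] = []
    seed_seq = np.random.SeedSequence(seed)
    sub_seeds = seed_seq.generate_state(len(pairs) * max(len(trait_leads), 1)) % (2**31)
    i = 0
    for pa, pb in pairs:
        mask_a = periods == pa
        mask_b = periods == pb
        fst = per_variant_fst(panel, mask_a, mask_b)
        for trait, idx in trait_leads.items():
            obs, n_used = mean_trait_fst(fst, idx)
            if n_used == 0:
                logger.warning("selection_scan: trait %s has no usable SNPs for %s-%s; skipped",
                               trait, pa, pb)
                i += 1
                continue
            null = build_matched_null(
                panel, np.asarray(idx, dtype=int), mask_a, mask_b,
                n_sets=n_sets, seed=int(sub_seeds[i]), fst=fst, ld=ld, **null_kwargs,
            )
            results.append(SelectionResult(
                trait=trait, period_a=pa, period_b=pb, n_snps=n_used,
                mean_fst=obs, null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)),
                p_empirical=empirical_two_tailed_p(obs, null),
                null_draws=null if keep_null else None,
            ))
            i += 1
    adj = bonferroni_adjust([r.p_empirical for r in results])
    for r, a in zip(results, adj):
        r.p_bonferroni = float(a)
    return results


def selection_results_frame(results: list[SelectionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": r.trait, "period_pair": f"{r.period_a}-{r.period_b}",
                "n_snps": r.n_snps, "mean_fst": r.mean_fst,
                "null_mean": r.null_mean, "null_sd": r.null_sd,
                "p_empirical": r.p_empirical, "p_bonferroni": r.p_bonferroni,
            }
            for r in results
        ]
    )
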