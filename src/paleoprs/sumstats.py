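"""GWAS/QTL summary-statistic tables: quality filters and allele alignment.

A summary-statistic table is a DataFrame with columns
``variant_id, chrom, pos, effect_allele, other_allele, beta, pvalue``.
``beta`` is the per-effect-allele additive weight on the 0-2 dosage scale;
one convention serves quantitative traits and case/control log-odds alike.

Pseudo-haploid ancient calls carry no strand information, so strand-ambiguous
SNPs (A/T and C/G pairs) must be excluded before aligning effect alleles to a
genotype panel; alignment accepts strand-complement matches only because of
that exclusion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panels import GenotypePanel

logger = logging.getLogger(__name__)

SUMSTAT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "pvalue"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


def read_sumstats(path: str, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-separated summary-statistics file (gzip accepted).

    ``column_map`` renames non-standard input columns, e.g.
    ``{"rsid": "variant_id", "OR_log": "beta"}``.
    """
    table = pd.read_csv(path, sep="\t", compression="infer",
                        dtype={"chrom": str, "variant_id": str})
    if column_map:
        table = table.rename(columns=column_map)
    missing = [c for c in SUMSTAT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing summary-statistic columns {missing}")
    table = table[SUMSTAT_COLUMNS].copy()
    table["chrom"] = table["chrom"].astype(str)
    table["pos"] = table["pos"].astype(int)
    for col in ("effect_allele", "other_allele"):
        table[col] = table[col].astype(str).str.upper()
    return table


def write_sumstats(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def filter_biallelic(table: pd.DataFrame) -> pd.DataFrame:
    """Keep single-nucleotide, bi-allelic records.

    Removes indels/multi-character alleles and every record at a
    (chrom, pos) whose pooled allele set exceeds two alleles (multi-allelic
    sites are dropped wholesale, not reduced to a best pair).
    """
    snv = (
        table["effect_allele"].isin(list("ACGT"))
        & table["other_allele"].isin(list("ACGT"))
        & (table["effect_allele"] != table["other_allele"])
    )
    table = table[snv]
    pooled = table.groupby(["chrom", "pos"]).apply(
        lambda g: len(set(g["effect_allele"]) | set(g["other_allele"])), include_groups=False
    )
    if len(pooled):
        bad = pooled[pooled > 2].index
        if len(bad):
            mask = ~pd.MultiIndex.from_frame(table[["chrom", "pos"]]).isin(bad)
            logger.info("filter_biallelic: removed %d records at %d multi-allelic sites",
                        int((~mask).sum()), len(bad))
            table = table[mask]
    dup = table.duplicated(subset=["chrom", "pos", "effect_allele", "other_allele"])
    if dup.any():
        logger.info("filter_biallelic: dropped %d duplicate records", int(dup.sum()))
        table = table[~dup]
    return table.reset_index(drop=True)


def drop_ambiguous(table: pd.DataFrame) -> pd.DataFrame:
    """Exclude strand-ambiguous SNPs (A/T and C/G allele pairs, either order)."""
    pairs = [
        {ea, oa} for ea, oa in zip(table["effect_allele"], table["other_allele"])
    ]
    keep = np.array([p not in _AMBIGUOUS_PAIRS for p in pairs])
    removed = int((~keep).sum())
    if removed:
        logger.info("drop_ambiguous: removed %d strand-ambiguous SNPs", removed)
    out = table[keep].reset_index(drop=True)
    if len(out) == 0 and len(table) > 0:
        logger.warning("drop_ambiguous: no records remain after the ambiguity filter")
    return out


def align_effect_alleles(table: pd.DataFrame, panel: GenotypePanel) -> pd.DataFrame:
    """Orient ``beta`` to the panel's counted allele (``allele1``).

    Matching is on (chrom, pos). Direct and strand-complement matches are
    accepted (call :func:`drop_ambiguous` first — complements of ambiguous
    pairs are indistinguishable from swaps); a swapped match negates beta via
    the dosage-complement identity ``X -> 2 - X``. Irreconcilable or absent
    records are dropped and counted. The output gains a ``panel_index``
    column and has ``effect_allele == allele1`` — re-alignment is a no-op.
    """
    pv = panel.variants
    lookup = pd.DataFrame(
        {
            "chrom": pv["chrom"].astype(str),
            "pos": pv["pos"].astype(int),
            "allele1": pv["allele1"],
            "allele2": pv["allele2"],
            "panel_index": np.arange(len(pv)),
        }
    )
    merged = table.merge(lookup, on=["chrom", "pos"], how="inner")
    n_absent = len(table) - len(merged)

    ea, oa = merged["effect_allele"], merged["other_allele"]
    cea = ea.map(_COMPLEMENT).fillna("?")
    coa = oa.map(_COMPLEMENT).fillna("?")
    a1, a2 = merged["allele1"], merged["allele2"]

    direct = (ea == a1) & (oa == a2)
    swapped = (ea == a2) & (oa == a1)
    comp_direct = (cea == a1) & (coa == a2)
    comp_swapped = (cea == a2) & (coa == a1)
    flip = (~direct) & (swapped | ((~comp_direct) & comp_swapped))
    ok = direct | swapped | comp_direct | comp_swapped

    out = merged[ok].copy()
    out["beta"] = np.where(flip[ok], -out["beta"], out["beta"])
    out["effect_allele"] = out["allele1"]
    out["other_allele"] = out["allele2"]
    out = out.drop(columns=["allele1", "allele2"])
    n_irrec = int((~ok).sum())
    if n_absent or n_irrec:
        logger.info(
            "align_effect_alleles: dropped %d records absent from the panel and "
            "%d with irreconcilable alleles", n_absent, n_irrec,
        )
    return out.reset_index(drop=True)


def select_by_pvalue(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep records with p strictly below ``threshold``, sorted ascending by p."""
    if not 0 < threshold <= 1:
        raise ValueError("p-value threshold must lie in (0, 1]")
    out = table[table["pvalue"] < threshold].sort_values(
        ["pvalue", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    if len(out) == 0:
        logger.warning("select_by_pvalue: no records below p < %g "
                       "(trait will be skipped downstream)", threshold)
    return out
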