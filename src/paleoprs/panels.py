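"""Genotype panels: containers, EIGENSTRAT/PLINK readers, cohort filters, merging.

A :class:`GenotypePanel` holds a samples x variants dosage matrix on the 0-2
effect-allele scale with ``NaN`` for missing calls. The counted allele is
always ``allele1`` of the variant table. Ancient samples are typically
pseudo-haploid: one sequencing read's allele is taken per site, so their
dosages are restricted to {0, 2, missing}; modern samples are diploid with
dosages in {0, 1, 2}.

All cohort filters log the number of removed samples/variants to stderr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .periods import DEFAULT_BOUNDS_BP, resolve_period

logger = logging.getLogger(__name__)

PSEUDO_HAPLOID = "pseudo_haploid"
DIPLOID = "diploid"

#: Default European sampling box: 35-70 degrees N, 10 degrees W - 40 degrees E.
DEFAULT_LAT_RANGE = (35.0, 70.0)
DEFAULT_LON_RANGE = (-10.0, 40.0)

VARIANT_COLUMNS = ["id", "chrom", "pos", "allele1", "allele2"]
META_COLUMNS = ["sample_id", "age_bp", "latitude", "longitude", "period"]


class PanelFormatError(ValueError):
    """Raised when a genotype file violates its format contract."""


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix plus per-sample ploidy mode.

    Attributes
    ----------
    sample_ids
        Ordered sample identifiers (rows of ``dosage``).
    variants
        Per-variant table with columns ``id, chrom, pos, allele1, allele2``;
        ``pos`` is 1-based bp. ``dosage`` counts copies of ``allele1``.
    dosage
        ``(n_samples, n_variants)`` float array; ``NaN`` marks missing calls.
    ploidy
        Per-sample mode, ``"pseudo_haploid"`` or ``"diploid"``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    ploidy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if self.ploidy is None:
            self.ploidy = self.infer_ploidy()
        self.ploidy = np.asarray(self.ploidy, dtype=object)
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def infer_ploidy(self) -> np.ndarray:
        """Fallback ploidy guess: any heterozygous call marks a sample diploid."""
        has_het = np.nansum(self.dosage == 1, axis=1) > 0
        return np.where(has_het, DIPLOID, PSEUDO_HAPLOID).astype(object)

    def missing_fraction(self) -> np.ndarray:
        """Per-sample fraction of missing calls (0 for a zero-variant panel)."""
        if self.n_variants == 0:
            return np.zeros(self.n_samples)
        return np.isnan(self.dosage).mean(axis=1)

    def variant_keys(self) -> pd.Index:
        """(chrom, pos, unordered allele set) keys used for cross-panel matching."""
        alleles = [
            "/".join(sorted((a1, a2)))
            for a1, a2 in zip(self.variants["allele1"], self.variants["allele2"])
        ]
        return pd.Index(list(zip(self.variants["chrom"], self.variants["pos"], alleles)))

    def subset_samples(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in index],
            variants=self.variants.copy(),
            dosage=self.dosage[index],
            ploidy=self.ploidy[index].copy(),
        )

    def subset_variants(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
            ploidy=self.ploidy.copy(),
        )

    def validate(self) -> None:
        """Check the panel invariants; raises ``ValueError`` on violation."""
        ph = np.asarray(self.ploidy) == PSEUDO_HAPLOID
        if ph.any() and np.nansum(self.dosage[ph] == 1) > 0:
            raise ValueError("pseudo-haploid sample carries a heterozygous dosage 1")
        if self.n_variants:
            if (self.variants["pos"] <= 0).any():
                raise ValueError("variant positions must be strictly positive")
            if self.variant_keys().duplicated().any():
                raise ValueError("duplicate (chrom, pos, allele-set) variant keys")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.isin(obs, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must lie in {0, 1, 2, missing}")


# ---------------------------------------------------------------------------
# EIGENSTRAT trio
# ---------------------------------------------------------------------------

def read_eigenstrat(prefix: str, ploidy: np.ndarray | None = None) -> GenotypePanel:
    """Read an EIGENSTRAT trio ``prefix.{geno,snp,ind}``.

    ``.geno`` holds one row per variant and one character per sample
    (0/1/2 copies of ``allele1``; 9 = missing). Sample order of ``.ind``
    is preserved. If ``ploidy`` is not given it is inferred from the calls
    (see :meth:`GenotypePanel.infer_ploidy`); prefer assigning it from the
    sample metadata via :func:`assign_ploidy`.
    """
    ind = pd.read_csv(
        f"{prefix}.ind", sep=r"\s+", header=None, names=["id", "sex", "population"],
        dtype=str,
    ) if _nonempty(f"{prefix}.ind") else pd.DataFrame(columns=["id", "sex", "population"])
    snp = pd.read_csv(
        f"{prefix}.snp", sep=r"\s+", header=None,
        names=["id", "chrom", "genetic_pos", "pos", "allele1", "allele2"],
        dtype={"id": str, "chrom": str, "allele1": str, "allele2": str},
    ) if _nonempty(f"{prefix}.snp") else pd.DataFrame(
        columns=["id", "chrom", "genetic_pos", "pos", "allele1", "allele2"]
    )
    n_samples, n_variants = len(ind), len(snp)

    rows = []
    with open(f"{prefix}.geno") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if len(line) != n_samples:
                raise PanelFormatError(
                    f"{prefix}.geno line {lineno}: expected {n_samples} genotype "
                    f"characters, found {len(line)}"
                )
            if not set(line) <= set("0129"):
                raise PanelFormatError(
                    f"{prefix}.geno line {lineno}: invalid genotype characters"
                )
            rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    if len(rows) != n_variants:
        raise PanelFormatError(
            f"{prefix}.geno has {len(rows)} variant rows but {prefix}.snp lists {n_variants}"
        )
    if rows:
        geno = np.vstack(rows).astype(float).T  # samples x variants
        geno[geno == 9] = np.nan
    else:
        geno = np.empty((n_samples, 0))

    variants = snp[VARIANT_COLUMNS].copy()
    variants["pos"] = variants["pos"].astype(int)
    return GenotypePanel(list(ind["id"]), variants, geno, ploidy)


def write_eigenstrat(panel: GenotypePanel, prefix: str, populations: list[str] | None = None) -> None:
    """Write ``prefix.{geno,snp,ind}``; missing dosages become 9."""
    geno = panel.dosage.T.copy()
    geno[np.isnan(geno)] = 9
    with open(f"{prefix}.geno", "w") as fh:
        for row in geno.astype(int):
            fh.write("".join(map(str, row)) + "\n")
    with open(f"{prefix}.snp", "w") as fh:
        for _, v in panel.variants.iterrows():
            fh.write(f"{v['id']}\t{v['chrom']}\t0.0\t{int(v['pos'])}\t{v['allele1']}\t{v['allele2']}\n")
    pops = populations if populations is not None else ["Unknown"] * panel.n_samples
    with open(f"{prefix}.ind", "w") as fh:
        for sid, pop in zip(panel.sample_ids, pops):
            fh.write(f"{sid}\tU\t{pop}\n")


def _nonempty(path: str) -> bool:
    import os

    return os.path.getsize(path) > 0


# ---------------------------------------------------------------------------
# PLINK binary trio (optional alternative input behind the same contract)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> allele1 dosage (01 = missing)
_BED_CODE_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str, ploidy: np.ndarray | None = None) -> GenotypePanel:
    """Read a variant-major PLINK ``.bed/.bim/.fam`` trio.

    Dosages count the ``.bim`` A1 allele, which becomes ``allele1`` of the
    panel, matching the EIGENSTRAT reader's convention.
    """
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(
        f"{prefix}.bim", sep=r"\s+", header=None,
        names=["chrom", "id", "genetic_pos", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "id": str, "allele1": str, "allele2": str},
    )
    n_samples, n_variants = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise PanelFormatError(f"{prefix}.bed: bad magic bytes (not variant-major PLINK)")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_variant = (n_samples + 3) // 4
    if raw.size != bytes_per_variant * n_variants:
        raise PanelFormatError(
            f"{prefix}.bed: {raw.size} data bytes, expected {bytes_per_variant * n_variants}"
        )
    raw = raw.reshape(n_variants, bytes_per_variant)
    # unpack 2-bit codes, sample-minor within each byte (LSB first)
    codes = np.empty((n_variants, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    dosage = _BED_CODE_DOSAGE[codes[:, :n_samples]].T
    variants = bim[VARIANT_COLUMNS].copy()
    variants["pos"] = variants["pos"].astype(int)
    return GenotypePanel(list(fam[1]), variants, dosage, ploidy)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(path: str) -> pd.DataFrame:
    """Read the metadata TSV (sample_id, age_bp, latitude, longitude[, period])."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "period": str})
    for col in ["sample_id", "age_bp", "latitude", "longitude"]:
        if col not in meta.columns:
            raise PanelFormatError(f"{path}: missing required column {col!r}")
    if "period" not in meta.columns:
        meta["period"] = pd.NA
    return meta


def write_sample_meta(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=False)


def assign_ploidy(panel: GenotypePanel, meta: pd.DataFrame, pseudo_haploid_periods) -> GenotypePanel:
    """Set per-sample ploidy from metadata period labels."""
    period = meta.set_index("sample_id")["period"]
    ploidy = np.array(
        [
            PSEUDO_HAPLOID if period.get(sid) in pseudo_haploid_periods else DIPLOID
            for sid in panel.sample_ids
        ],
        dtype=object,
    )
    return replace(panel, ploidy=ploidy)


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------

def filter_samples_missingness(panel: GenotypePanel, max_missing: float = 0.96) -> GenotypePanel:
    """Drop samples whose missing-call fraction is strictly above ``max_missing``.

    The boundary sample (fraction exactly equal to the threshold) is kept:
    only "above" is filtered, to remove extreme low-coverage outliers.
    """
    if not 0 < max_missing <= 1:
        raise ValueError("max_missing must lie in (0, 1]")
    frac = panel.missing_fraction()
    keep = np.flatnonzero(frac <= max_missing)
    removed = panel.n_samples - keep.size
    if removed:
        logger.info("missingness filter (> %.2f): removed %d of %d samples",
                    max_missing, removed, panel.n_samples)
    return panel.subset_samples(keep)


def filter_geobox(
    meta: pd.DataFrame,
    lat_range: tuple[float, float] = DEFAULT_LAT_RANGE,
    lon_range: tuple[float, float] = DEFAULT_LON_RANGE,
) -> pd.DataFrame:
    """Keep samples inside the (inclusive) latitude/longitude box; drop samples
    lacking coordinates."""
    if lat_range[0] > lat_range[1] or lon_range[0] > lon_range[1]:
        raise ValueError("coordinate ranges must be ordered (low, high)")
    lat = pd.to_numeric(meta["latitude"], errors="coerce")
    lon = pd.to_numeric(meta["longitude"], errors="coerce")
    keep = (
        lat.between(lat_range[0], lat_range[1], inclusive="both")
        & lon.between(lon_range[0], lon_range[1], inclusive="both")
    )
    removed = int((~keep.fillna(False)).sum())
    if removed:
        logger.info("geographic box filter: removed %d of %d samples", removed, len(meta))
    return meta[keep.fillna(False)].reset_index(drop=True)


def assign_periods(meta: pd.DataFrame, bounds: dict | None = None) -> pd.DataFrame:
    """Assign broad time periods from carbon-dated ages.

    An explicit ``period`` label in the input always wins (labels encode
    archaeological context the age alone cannot resolve). Unlabeled samples
    are placed by their age; overlap zones resolve to the nearest interval
    midpoint. Samples whose age matches no interval get ``period = NaN``
    and a warning; downstream stages exclude them.
    """
    bounds = DEFAULT_BOUNDS_BP if bounds is None else bounds
    meta = meta.copy()
    if (pd.to_numeric(meta["age_bp"], errors="coerce") < 0).any():
        raise ValueError("age_bp must be non-negative (years before 1950)")
    assigned = []
    n_unassigned = 0
    for _, row in meta.iterrows():
        label = row.get("period")
        if isinstance(label, str) and label:
            assigned.append(label)
            continue
        period = resolve_period(float(row["age_bp"]), bounds)
        if period is None:
            n_unassigned += 1
        assigned.append(period)
    meta["period"] = pd.array(assigned, dtype="object")
    if n_unassigned:
        logger.warning("%d samples could not be assigned a period and will be "
                       "excluded downstream", n_unassigned)
    return meta


# ---------------------------------------------------------------------------
# Variant intersection / panel merging
# ---------------------------------------------------------------------------

def intersect_variants(ancient: GenotypePanel, modern: GenotypePanel) -> GenotypePanel:
    """Merge two panels over their shared variants.

    Variants are matched on ``(chrom, pos, unordered allele set)``. The merged
    panel keeps the ancient panel's allele orientation; modern dosages at
    variants whose counted allele is swapped are recoded ``X -> 2 - X``.
    Same-position variants with incompatible allele sets are dropped and
    counted in the log. Sample order: ancient samples first, then modern.
    """
    a_keys, m_keys = ancient.variant_keys(), modern.variant_keys()
    shared = a_keys.intersection(m_keys)
    n_pos_clash = len(
        set(zip(ancient.variants["chrom"], ancient.variants["pos"]))
        & set(zip(modern.variants["chrom"], modern.variants["pos"]))
    ) - len(shared)
    if n_pos_clash > 0:
        logger.info("intersect_variants: dropped %d same-position variants with "
                    "incompatible allele sets", n_pos_clash)
    if len(shared) == 0:
        logger.warning("intersect_variants: the two panels share no variants")
    a_idx = np.flatnonzero(a_keys.isin(shared))
    a_sub = ancient.subset_variants(a_idx)
    m_lookup = pd.Series(np.arange(len(m_keys)), index=m_keys)
    m_idx = m_lookup.loc[a_keys[a_idx]].to_numpy()
    m_sub = modern.subset_variants(m_idx)

    # reorient modern dosages where the counted allele differs
    swapped = (m_sub.variants["allele1"].to_numpy() != a_sub.variants["allele1"].to_numpy())
    m_dos = m_sub.dosage.copy()
    m_dos[:, swapped] = 2.0 - m_dos[:, swapped]

    return GenotypePanel(
        sample_ids=list(a_sub.sample_ids) + list(m_sub.sample_ids),
        variants=a_sub.variants.copy(),
        dosage=np.vstack([a_sub.dosage, m_dos]) if (a_sub.n_samples + m_sub.n_samples) else
        np.empty((0, a_sub.n_variants)),
        ploidy=np.concatenate([a_sub.ploidy, m_sub.ploidy]),
    )


def restrict_to_meta(panel: GenotypePanel, meta: pd.DataFrame) -> tuple[GenotypePanel, pd.DataFrame]:
    """Keep samples present in both the panel and the metadata, panel order."""
    known = set(meta["sample_id"])
    keep = np.flatnonzero([sid in known for sid in panel.sample_ids])
    panel = panel.subset_samples(keep)
    meta = meta.set_index("sample_id").loc[panel.sample_ids].reset_index()
    return panel, meta
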