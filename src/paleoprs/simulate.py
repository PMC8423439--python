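"""Synthetic time-stamped cohorts: Wright-Fisher drift, pseudo-haploid sampling,
and GWAS-style summary statistics with planted effects.

The generator emulates the structure of a compiled ancient-DNA panel merged
with modern references: carbon-dated samples spread over six broad periods
(EUP through Modern), pseudo-haploid {0, 2} calls with heavy per-call
missingness for the ancient samples, diploid calls at age 0 for the modern
ones, and a tab-separated summary-statistic table whose trait variants carry
real effects and may experience directional selection during the
post-Neolithic epoch.

Allele frequencies follow independent-locus Wright-Fisher dynamics: each
generation applies the deterministic genic-selection update
``p' = p (1 + s) / (1 + p s)`` to the favored allele (identity at s = 0) and
then resamples ``effective_size`` chromosomes binomially. Each sample draws
its alleles from the trajectory generation matching its carbon-dated age
(piecewise-linear age-to-generation map with its knot at the Neolithic
boundary), so selected alleles rise *within* the post-Neolithic epoch, not
just between epochs. Every simulation is a pure function of the seed.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import panels
from .panels import DIPLOID, PSEUDO_HAPLOID, GenotypePanel

logger = logging.getLogger(__name__)

ANCIENT_PERIODS = ("EUP", "LUP", "Mesolithic", "Neolithic", "PostNeolithic")

#: Default per-period sample counts: 827 ancient + 250 modern, with scarce
#: pre-Neolithic representation, mirroring compiled-aDNA cohort composition.
DEFAULT_SAMPLE_COUNTS: dict[str, int] = {
    "EUP": 14, "LUP": 36, "Mesolithic": 119,
    "Neolithic": 274, "PostNeolithic": 384, "Modern": 250,
}

#: Non-overlapping age sampling ranges (years BP) per period, chosen inside
#: the archaeological bounds so the generated labels and ages are consistent.
DEFAULT_AGE_RANGES: dict[str, tuple[int, int]] = {
    "EUP": (27000, 40000),
    "LUP": (13000, 26950),
    "Mesolithic": (10500, 12950),
    "Neolithic": (5900, 10450),
    "PostNeolithic": (100, 5850),
    "Modern": (0, 0),
}

DEFAULT_MISSING_RATE: dict[str, float] = {
    **{p: 0.65 for p in ANCIENT_PERIODS}, "Modern": 0.0,
}

_NONAMBIGUOUS_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                       ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    effective_size
        Wright-Fisher population size in *chromosomes* (2N). The default
        100,000 reflects a large post-glacial European population, keeping
        between-epoch drift subordinate to pseudo-haploid sampling noise.
    generations_pre, generations_post
        Drift generations before/after the Neolithic boundary; selection, if
        any, acts only during the post epoch.
    selection_coeff
        Genic selection coefficient (>= -1) applied to each trait variant's
        trait-increasing allele; scalar or per-trait-variant array. 0 = neutral.
    beta_scale
        SD of true trait-variant effects; estimated effects add Gaussian noise
        with ``se = beta_scale / sqrt(n_gwas)``.
    ambiguous_fraction
        Fraction of variants given strand-ambiguous (A/T, C/G) allele pairs,
        to exercise the ambiguity filter downstream.
    """

    seed: int = 0
    n_variants: int = 1200
    n_trait_variants: int = 20
    effective_size: int = 100_000
    generations_pre: int = 600
    generations_post: int = 200
    selection_coeff: float | tuple = 0.0
    sample_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SAMPLE_COUNTS))
    missing_rate: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSING_RATE))
    pseudo_haploid_periods: frozenset = frozenset(ANCIENT_PERIODS)
    beta_scale: float = 0.1
    n_gwas: int = 500
    ambiguous_fraction: float = 0.1
    init_freq_range: tuple[float, float] = (0.05, 0.95)
    age_ranges: Mapping[str, tuple[int, int]] = field(default_factory=lambda: dict(DEFAULT_AGE_RANGES))

    def __post_init__(self) -> None:
        if self.n_trait_variants > self.n_variants:
            raise ConfigError("n_trait_variants must not exceed n_variants")
        if self.effective_size < 2:
            raise ConfigError("effective_size must be at least 2 chromosomes")
        s = np.atleast_1d(np.asarray(self.selection_coeff, dtype=float))
        if not np.isfinite(s).all() or (s < -1).any():
            raise ConfigError("selection coefficients must be finite and >= -1")
        for p, r in self.missing_rate.items():
            if not 0 <= r < 1:
                raise ConfigError(f"missing_rate[{p!r}] must lie in [0, 1)")
        if self.beta_scale <= 0:
            raise ConfigError("beta_scale must be positive")
        lo, hi = self.init_freq_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("init_freq_range must be an ordered subinterval of [0, 1]")
        if self.ambiguous_fraction < 0 or self.ambiguous_fraction > 1:
            raise ConfigError("ambiguous_fraction must lie in [0, 1]")

    @property
    def selection_per_trait_variant(self) -> np.ndarray:
        s = np.atleast_1d(np.asarray(self.selection_coeff, dtype=float))
        if s.size == 1:
            return np.full(self.n_trait_variants, float(s[0]))
        if s.size != self.n_trait_variants:
            raise ConfigError("selection_coeff length must equal n_trait_variants")
        return s

    @property
    def total_generations(self) -> int:
        return self.generations_pre + self.generations_post

    @property
    def neolithic_boundary_bp(self) -> int:
        """Age at which the post epoch (and selection) begins."""
        return self.age_ranges["Neolithic"][1]

    @property
    def oldest_age_bp(self) -> int:
        return max(hi for _, hi in self.age_ranges.values())


@dataclass
class SimulatedPanel:
    """One synthetic cohort: genotypes, metadata, summary statistics, truth."""

    panel: GenotypePanel
    meta: pd.DataFrame
    sumstats: pd.DataFrame
    truth: dict


def selection_update(p: np.ndarray, s: np.ndarray, favored_allele1: np.ndarray) -> np.ndarray:
    """One generation of deterministic genic selection.

    Where the favored allele is allele 1: ``p' = p (1 + s) / (1 + p s)``;
    where it is allele 2 the symmetric update ``p' = p / (1 + (1 - p) s)``
    applies. Fixed loci (p = 0 or 1) are absorbing under any s.
    """
    p = np.asarray(p, dtype=float)
    s = np.asarray(s, dtype=float)
    up1 = p * (1 + s) / (1 + p * s)
    up2 = p / (1 + (1 - p) * s)
    return np.where(favored_allele1, up1, up2)


def age_to_generation(age_bp: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Piecewise-linear map from years BP to trajectory generation index.

    Generation 0 is the oldest sampled age; the Neolithic boundary maps to
    ``generations_pre``; age 0 maps to the final generation.
    """
    age_bp = np.asarray(age_bp, dtype=float)
    knot = float(config.neolithic_boundary_bp)
    oldest = float(config.oldest_age_bp)
    g_pre, g_post = config.generations_pre, config.generations_post
    pre = np.rint((oldest - age_bp) / (oldest - knot) * g_pre)
    post = g_pre + np.rint((knot - age_bp) / knot * g_post)
    gen = np.where(age_bp > knot, pre, post)
    return np.clip(gen, 0, g_pre + g_post).astype(int)


def simulate_frequencies(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    favored_allele1: np.ndarray | None = None,
) -> np.ndarray:
    """Per-variant allele-1 frequency trajectories, shape
    ``(total_generations + 1, n_variants)``; row 0 holds the initial draws.

    Neutral variants drift by pure binomial resampling of ``effective_size``
    chromosomes; the first ``n_trait_variants`` variants additionally get the
    deterministic selection update during the post epoch, directed at allele 1
    unless ``favored_allele1`` marks allele 2 as trait-increasing.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = config.n_variants
    lo, hi = config.init_freq_range
    s_full = np.zeros(m)
    s_full[: config.n_trait_variants] = config.selection_per_trait_variant
    fav = np.ones(m, dtype=bool)
    if favored_allele1 is not None:
        fav[: config.n_trait_variants] = np.asarray(favored_allele1, dtype=bool)

    traj = np.empty((config.total_generations + 1, m))
    traj[0] = rng.uniform(lo, hi, size=m)
    size = config.effective_size
    p = traj[0]
    for g in range(1, config.total_generations + 1):
        in_post = g > config.generations_pre
        if in_post and np.any(s_full != 0):
            p = selection_update(p, s_full, fav)
        p = rng.binomial(size, p) / size
        traj[g] = p
    return traj


def sample_genotypes(
    frequencies: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    variants: pd.DataFrame | None = None,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Draw genotyped samples period by period from the frequency trajectories.

    Each sample gets an integer age uniform in its period's range (Modern
    age = 0) and draws alleles from the trajectory generation matching that
    age. Pseudo-haploid samples observe a single allele per site (dosage 0
    or 2); diploid samples draw Binomial(2, p). Calls then go missing
    independently at the period's missing rate. Coordinates are drawn inside
    the default European box.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if variants is None:
        variants = make_variant_table(config, np.random.default_rng(config.seed))
    from .periods import PERIOD_ORDER

    sample_rows = []
    dosages = []
    ploidy = []
    counter = 0
    for period in PERIOD_ORDER:
        if period not in config.sample_counts:
            continue
        count = int(config.sample_counts[period])
        if count == 0:
            logger.warning("sample_genotypes: empty sample request for period %s; skipping", period)
            continue
        lo, hi = config.age_ranges[period]
        ages = (np.zeros(count, dtype=int) if period == "Modern"
                else rng.integers(lo, hi + 1, size=count))
        gens = age_to_generation(ages, config)
        is_ph = period in config.pseudo_haploid_periods
        miss = float(config.missing_rate.get(period, 0.0))
        lats = np.round(rng.uniform(36.0, 69.0, size=count), 3)
        lons = np.round(rng.uniform(-9.0, 39.0, size=count), 3)
        for i in range(count):
            p = frequencies[gens[i]]
            if is_ph:
                dos = 2.0 * (rng.random(config.n_variants) < p)
            else:
                dos = rng.binomial(2, p).astype(float)
            if miss > 0:
                dos[rng.random(config.n_variants) < miss] = np.nan
            dosages.append(dos)
            ploidy.append(PSEUDO_HAPLOID if is_ph else DIPLOID)
            sample_rows.append({
                "sample_id": f"{period}_{counter:04d}", "age_bp": int(ages[i]),
                "latitude": lats[i], "longitude": lons[i], "period": period,
            })
            counter += 1
    meta = pd.DataFrame(sample_rows, columns=panels.META_COLUMNS)
    dosage = np.vstack(dosages) if dosages else np.empty((0, config.n_variants))
    panel = GenotypePanel(list(meta["sample_id"]), variants, dosage,
                          np.array(ploidy, dtype=object))
    return panel, meta


def make_variant_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant map: ids, chromosomes 1-22 round-robin, unique positions,
    allele pairs with an ``ambiguous_fraction`` share of A/T / C/G pairs."""
    m = config.n_variants
    chroms = (np.arange(m) % 22 + 1).astype(str)
    pos = np.zeros(m, dtype=int)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        pos[idx] = np.sort(rng.choice(130_000_000, size=idx.size, replace=False) + 1)
    ambiguous = rng.random(m) < config.ambiguous_fraction
    pair_idx = rng.integers(0, len(_NONAMBIGUOUS_PAIRS), size=m)
    amb_idx = rng.integers(0, len(_AMBIGUOUS_PAIRS), size=m)
    a1 = np.where(ambiguous,
                  [p[0] for p in np.array(_AMBIGUOUS_PAIRS, dtype=object)[amb_idx]],
                  [p[0] for p in np.array(_NONAMBIGUOUS_PAIRS, dtype=object)[pair_idx]])
    a2 = np.where(ambiguous,
                  [p[1] for p in np.array(_AMBIGUOUS_PAIRS, dtype=object)[amb_idx]],
                  [p[1] for p in np.array(_NONAMBIGUOUS_PAIRS, dtype=object)[pair_idx]])
    return pd.DataFrame({
        "id": [f"var{i:06d}" for i in range(m)],
        "chrom": chroms, "pos": pos, "allele1": a1, "allele2": a2,
    })


def emit_sumstats(
    truth: dict,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """GWAS-style summary statistics for every panel variant.

    True effects ``beta`` (non-zero for trait variants only) receive Gaussian
    estimation noise with ``se = beta_scale / sqrt(n_gwas)``; the reported
    p-value is the two-sided Wald p of ``z = beta_hat / se``, so null
    variants get uniform p-values and large effects small ones. Effect/other
    alleles are emitted in panel orientation or swapped (with negated beta)
    with probability 1/2, exercising downstream allele alignment.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    variants: pd.DataFrame = truth["variants"]
    beta_true: np.ndarray = truth["beta_true"]
    se = config.beta_scale / np.sqrt(config.n_gwas)
    beta_hat = beta_true + rng.normal(0.0, se, size=len(variants))
    z = beta_hat / se
    pvalue = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    swap = rng.random(len(variants)) < 0.5
    ea = np.where(swap, variants["allele2"], variants["allele1"])
    oa = np.where(swap, variants["allele1"], variants["allele2"])
    return pd.DataFrame({
        "variant_id": variants["id"],
        "chrom": variants["chrom"],
        "pos": variants["pos"],
        "effect_allele": ea,
        "other_allele": oa,
        "beta": np.where(swap, -beta_hat, beta_hat),
        "pvalue": pvalue,
    })


def generate_panel(config: SimulationConfig, out_dir: str | None = None,
                   trait_name: str = "trait") -> SimulatedPanel:
    """Generate a full cohort; optionally write it as EIGENSTRAT trios + TSVs.

    Sub-stage RNG streams (effects, frequencies, genotypes, summary noise)
    are spawned deterministically from the single seed, so identical configs
    produce bit-identical cohorts and files. When ``out_dir`` is given the
    ancient and modern samples are written as separate trios
    (``ancient.*`` / ``modern.*``) plus ``samples.tsv`` and
    ``sumstats_<trait>.tsv``, all round-tripping exactly through the readers.
    """
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)]
    rng_beta, rng_freq, rng_geno, rng_sum = streams

    beta_true = np.zeros(config.n_variants)
    beta_true[: config.n_trait_variants] = rng_beta.normal(
        0.0, config.beta_scale, size=config.n_trait_variants
    )
    variants = make_variant_table(config, rng_beta)
    # selection acts on the trait-increasing allele: allele1 iff beta >= 0
    favored_allele1 = beta_true[: config.n_trait_variants] >= 0

    frequencies = simulate_frequencies(config, rng_freq, favored_allele1)
    panel, meta = sample_genotypes(frequencies, config, rng_geno, variants)
    truth = {
        "variants": variants,
        "beta_true": beta_true,
        "selection_coeff": config.selection_per_trait_variant,
        "favored_allele1": favored_allele1,
        "frequencies": frequencies,
        "trait_variant_index": np.arange(config.n_trait_variants),
    }
    sumstats = emit_sumstats(truth, config, rng_sum)
    sim = SimulatedPanel(panel=panel, meta=meta, sumstats=sumstats, truth=truth)
    if out_dir is not None:
        write_simulated(sim, out_dir, trait_name)
    return sim


def write_simulated(sim: SimulatedPanel, out_dir: str, trait_name: str = "trait") -> None:
    """Write ancient/modern EIGENSTRAT trios, metadata TSV, and sumstats TSV."""
    os.makedirs(out_dir, exist_ok=True)
    ancient_mask = np.asarray(sim.meta["period"] != "Modern")
    for name, mask in (("ancient", ancient_mask), ("modern", ~ancient_mask)):
        sub = sim.panel.subset_samples(np.flatnonzero(mask))
        pops = list(sim.meta.loc[mask, "period"])
        panels.write_eigenstrat(sub, os.path.join(out_dir, name), populations=pops)
    panels.write_sample_meta(sim.meta, os.path.join(out_dir, "samples.tsv"))
    from .sumstats import write_sumstats

    write_sumstats(sim.sumstats, os.path.join(out_dir, f"sumstats_{trait_name}.tsv"))


def checksum_dir(out_dir: str) -> dict[str, str]:
    """SHA-256 of every file under ``out_dir`` (determinism checks)."""
    out = {}
    for name in sorted(os.listdir(out_dir)):
        path = os.path.join(out_dir, name)
        if os.path.isfile(path):
            out[name] = hashlib.sha256(open(path, "rb").read()).hexdigest()
    return out
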