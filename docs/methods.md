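# Methods

## Scope and data model

The pipeline operates on three inputs: a genotype panel of ancient samples
(pseudo-haploid calls: one sequencing read's allele per site, coded 0/2 with
9 = missing in EIGENSTRAT), a panel of modern diploid references, and
per-trait GWAS/QTL summary statistics. Dosages always count copies of the
panel's `allele1`; all downstream statistics are defined on that 0–2 scale.
Ages are years before present standardized to 1950 (BP = BCE + 1950); modern
samples sit at age 0.

### Period assignment

Default bounds (inclusive, in BCE): EUP before 25,000; LUP 25,000–11,000;
Mesolithic 11,000–5,500; Neolithic 8,500–3,900; post-Neolithic 5,000 onward;
Modern = age 0 exactly. The Mesolithic/Neolithic and Neolithic/post-Neolithic
ranges genuinely overlap; an explicit period label in the metadata always
wins, because labels encode archaeological context that a radiocarbon age
alone cannot resolve. An unlabeled sample in an overlap zone is assigned to
the interval whose midpoint is nearest — a deterministic stand-in for
evidence the pipeline does not have. Ages covered by no interval are flagged
and excluded downstream with a warning.

### Cohort filters

* Sample missingness: a sample is removed when its missing-call fraction is
  *strictly above* the threshold (default 0.96; the supported grid includes
  0.96/0.90/0.80/0.70). The boundary sample is kept — the filter's purpose is
  to drop extreme low-coverage outliers, not to trim the distribution.
* Geography: the European box 35–70°N × 10°W–40°E, boundaries inclusive
  (a measure-zero choice); samples without coordinates are dropped. The box
  applies to excavated (ancient) samples; modern references are assumed
  pre-selected.
* Variant intersection: ancient and modern panels are merged on
  (chromosome, position, unordered allele pair). The merged orientation is the
  ancient panel's; a modern variant whose counted allele is swapped is recoded
  X → 2 − X. Same-position variants with incompatible allele sets are dropped
  and counted in the log.

## Summary-statistic harmonization

Only single-nucleotide bi-allelic records survive; a position whose pooled
allele set exceeds two is removed wholesale. Strand-ambiguous SNPs (A/T, C/G)
are excluded *before* alignment — pseudo-haploid data carry no strand
information, so a strand flip at an ambiguous site is undetectable and would
silently negate an effect. Alignment to the panel then accepts direct and
strand-complement matches, negating β when the effect allele matches the
panel's other allele (dosage-complement identity X → 2 − X). β is treated as
a per-effect-allele additive weight for all traits, quantitative or
case/control, since one scoring formula is applied throughout. The p-value
threshold is strict (p < t), and records absent from the panel are dropped
before clumping so they cannot consume window budget.

## Polygenic scores

Clumping is greedy: take the most significant remaining record, discard
in-window neighbors (|Δpos| ≤ window, same chromosome, window inclusive),
repeat. Ties in p break on (chrom, pos) so results are platform-independent.
The LD-aware variant discards only in-window records with r² > 0.2 to the
lead; r² is the squared Pearson correlation of dosages over
pairwise-complete calls of the modern diploid samples only — pseudo-haploid
calls inflate apparent LD because hets are unobservable — and a pair with
fewer than two complete observations is treated as unknown LD and retained.

Scores are S = Σ Xβ with mean-dosage imputation: a missing dosage is
replaced by the variant's mean genotyped dosage over the entire merged
panel, so imputation pulls toward the cohort average and a fully missing
sample receives exactly the population-average score. Scores are min–max
scaled to [−1, 1] per trait over all samples jointly (ancient + modern); a
degenerate all-equal score vector maps to 0.

Two properties of this (deliberately simple, data-scarcity-driven)
imputation scheme matter for interpretation:

* it compresses the variance of high-missingness samples — the scale, not
  the direction, of temporal trends is affected;
* because every high-missingness sample shares the *same* estimated mean
  dosages, their scores carry a small common random offset relative to fully
  genotyped (modern) samples. In the trend test this behaves like a mild
  positive dependence between ancient samples and makes the OLS p-value
  slightly anti-conservative (we measure ≈ 6% rejection at nominal 5% under
  a fully neutral simulation). This is intrinsic to dataset-average
  imputation, not to the implementation; the selection test, whose null is
  resampled from the same panel, does not inherit it.

## Temporal trends

Age is the x-axis in years BP, so "rising toward the present" appears as
r < 0. Trends are summarized as sign(r)·(−log₁₀ p) with p floored at the
smallest positive double so the summary stays finite. The piecewise model
fits two independent OLS lines: pre-Neolithic (EUP, LUP, Mesolithic) and
Neolithic-and-later (including Modern at age 0); a side with fewer than
three samples is reported NA rather than fit. The breakpoint is fixed by the
period labels — no change-point estimation. Group comparisons use Student's
pooled-variance t (two-sided) between chronologically adjacent represented
periods plus a one-way ANOVA across all of them; a zero-pooled-variance pair
with unequal means is reported as the p → 0 limit with a `degenerate` flag.

LOESS uses local quadratic fits with tri-cube weights over the span fraction
(default 0.75) of nearest neighbors, evaluated on a 100-point uniform age
grid; the degree drops locally if too few positively weighted points remain.
Regression uncertainty elsewhere is the pointwise OLS band; no bootstrap.

Down-sampling robustness: the post-Neolithic side is repeatedly sampled
without replacement to the pre-Neolithic sample size (default 100
replicates) and the post-side correlation recomputed; the report is the
replicate mean, SD, and the fraction agreeing in sign with the full-data
coefficient.

## Selection test

Allele frequencies per period group count a pseudo-haploid call as one
chromosome and a diploid call as two; a variant unobserved in a group is
excluded from that comparison. Differentiation uses the Hudson estimator
with finite-sample correction,

  F̂st = [(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)] / [p₁(1−p₂) + p₂(1−p₁)],

chosen for robustness to small and unequal chromosome counts — the norm for
pseudo-haploid period groups. It is undefined (variant excluded) when either
n < 2 or the denominator is 0. The trait statistic is the plain mean of
per-SNP Fst over the trait's usable lead SNPs (a ratio-of-averages variant
is available via `mean_trait_fst_components`).

The null resamples background variants matched to the trait SNPs on
panel-wide minor-allele-frequency bin (width 0.05) and LD-score stratum
(quintiles of Σ r² to variants within 1 Mb, modern samples). Each of the
10,000 null sets draws one background variant per trait SNP from the same
cell, without replacement within a set, and takes the same mean-Fst
statistic. Empty cells fall back to the nearest non-empty MAF bin within the
LD stratum (logged). The two-tailed empirical p uses the add-one rule
p = min(1, 2·min[(1+#{null ≥ obs}), (1+#{null ≤ obs})]/(N+1)), which cannot
fall below 1/(N+1); Bonferroni correction spans every trait × period-pair
test actually performed in a run (the family size is reported).

The matching scheme assumes the background is much larger than the trait
set — trivially true on real panels (~10⁶ variants vs tens of SNPs). When a
matching cell holds only a handful of background variants, excluding the
trait SNPs from the pool biases the null and the test becomes
anti-conservative; synthetic experiments should keep at least ~50×
background-to-trait ratio.

## Synthetic cohorts

The generator emulates a compiled ancient-DNA panel merged with modern
references. What it reproduces: per-period sample counts (default 827
ancient + 250 modern, with scarce pre-Neolithic representation:
14/36/119/274/384 across EUP→post-Neolithic), pseudo-haploid {0,2} calls
with per-call missingness (default 0.65 for ancient samples, 0 for modern),
carbon-dated ages uniform within non-overlapping period ranges, coordinates
inside the European box, and summary statistics with planted effects. What
it does not reproduce: linkage (loci are independent — LD structure in real
panels is emulated only through the matching covariates), admixture and
migration pulses (Anatolian/Yamnaya turnover), reference bias, and
post-mortem damage. Passing tests therefore demonstrate the statistical
machinery under drift + genic selection, not robustness to demographic
confounding — which is precisely the confounder the matched-null test is
designed to flag, not to remove.

Dynamics: independent Wright–Fisher loci with initial frequencies uniform on
[0.05, 0.95]; per generation, the deterministic genic-selection update
p′ = p(1+s)/(1+ps) on the trait-increasing allele (allele 2's symmetric form
when β < 0; identity at s = 0, boundaries absorbing) followed by binomial
resampling of the `effective_size` chromosomes. Selection acts only during
the post-Neolithic epoch. Each sample draws alleles from the trajectory
generation matching its age via a piecewise-linear map (knot at the
Neolithic boundary, 10,450 BP), so selected alleles rise *within* the post
epoch rather than jumping between epochs — a sampled time series, which is
what the trend machinery is meant to detect.

Parameter defaults, chosen once as study conditions:

* `effective_size` = 100,000 chromosomes. Holocene European effective size
  grew far beyond the canonical long-term Nₑ ≈ 10⁴; a large value keeps
  between-epoch drift subordinate to pseudo-haploid sampling noise, which is
  also the regime in which the score–age trend test is approximately
  calibrated under neutrality.
* `generations_post` = 200 for the ~10,500 years of the post epoch,
  `generations_pre` = 600 for the ~30,000 years before it (a coarse ~50-year
  drift step; with large Nₑ only the product of generations and 1/Nₑ
  matters).
* `beta_scale` = 0.1 (SD of true effects) and `n_gwas` = 500, mirroring a
  cytokine-QTL-cohort scale; estimated effects are β̂ = β + N(0, se) with
  se = beta_scale/√n_gwas, and reported p-values are two-sided Wald p of
  β̂/se, so null variants are uniform and strong effects are significant.
  There is no claim that this is the generative model of any real QTL study;
  it is the simplest scheme with the right operating characteristics.
* `ambiguous_fraction` = 0.1 of variants receive A/T or C/G allele pairs so
  the ambiguity filter is exercised end to end; summary statistics are
  emitted with randomly swapped allele orientation to exercise alignment.
* One master seed; sub-stage generators (effects, frequencies, genotypes,
  summary noise) are spawned deterministically from it, so an identical
  configuration reproduces bit-identical cohorts and files.

## Numerical and degenerate-case choices

* p-values are floored at the smallest positive double before −log₁₀.
* Clumping tie-break: (p, chrom, pos) lexicographic.
* Mean dosages for imputation are recomputed on the refiltered panel in
  every robustness-grid cell, since each missingness threshold defines a
  different "entire dataset".
* Grid cells with no selected variants or fewer than three samples are NA,
  never silently skipped.
* A variant with zero genotyped calls is excluded from scoring; an
  all-missing sample is scored (population average) and flagged via
  `n_imputed`.
* Empirical p-values use the add-one rule and are capped at 1.

## Problem sizes used in the checks

The statistical test-bed runs at reduced but representative sizes chosen to
keep Monte-Carlo error well below the asserted margins: selection-test
calibration over 500 neutral replicates (999 null sets, 20 trait SNPs,
three-period cohorts), power over 100 replicates with s = 0.05, trend-test
type-I over 1,000 neutral replicates, and oracle equivalences over 50–100
random instances. The full-scale worked example (1,077 samples, 10,000 null
sets) runs in about a minute.

## Known limitations

* Independent-locus simulation: clumping on synthetic data rarely removes
  anything (variants are ~2.4 Mb apart on average), so window-size
  robustness is exercised structurally, not stressed.
* The trend test inherits mild anti-conservatism from shared mean-dosage
  imputation (above); treat post-side p-values near 0.05 with caution and
  rely on the selection test for selection claims.
* No ancestry-covariate correction: a real cohort's admixture turnover can
  produce PRS trends without selection; the matched-null Fst test flags
  differentiation beyond drift but cannot attribute it to selection vs
  migration.
* The PLINK reader supports the variant-major layout only.
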