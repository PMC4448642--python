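# Methods

This document describes the statistical models, algorithms, and numerical
choices implemented in `doscomp`, together with the scope of the synthetic
data generator and known limitations.

## 1. Data model and preprocessing (`doscomp.core_io`)

### Inputs

- **Count matrices** (genes × samples) of non-negative integer read counts,
  for mRNA and genomic DNA sequencing, with per-gene lengths.
- **Gene annotation**: chromosome, coordinates, and a subtelomeric flag.
  When chromosome lengths are supplied, genes within 25 kb of either
  chromosome end are flagged subtelomeric.
- **Sample sheet**: sample, strain, assay (mRNA/DNA), dose (e.g. 2n/3n/4n),
  replicate, and the paired euploid reference sample.

### Abundance and ratios

Counts are converted to RPKM (reads per kilobase per million mapped reads).
Log2 ratios are computed per gene between a test sample and its paired
euploid reference:

    y_g = log2((RPKM_test + c) / (RPKM_ref + c))

with a pseudocount `c` (default 0.5 for mRNA, 0 for DNA). Genes whose
abundance falls below a minimum (default RPKM 1.0 in either sample) are
dropped and reported. Ratios may optionally be median-centred per sample
using genes outside the amplified region, which removes global composition
shifts introduced by large aneuploidies.

### Ratio panels and DNA-dose stabilisation

A *ratio panel* is the long-format table (gene, sample, dose, x, y) where
`x` is the gene's measured DNA log2 ratio (averaged over DNA replicates) and
`y` the mRNA log2 ratio. Because all genes on one amplified chromosome share
a true copy number, per-gene DNA ratios are shrunk toward the chromosome
median with an empirical-Bayes weight

    w = v_between / (v_between + v_meas),   v_meas = median(rep. variance)/n_reps

computed per strain and chromosome. This attenuates regression-dilution bias
in the downstream dose–response fits while preserving genuine per-gene copy
variation (e.g. segmental amplifications). It requires at least two DNA
replicates and three genes per chromosome, and can be disabled
(`shrink_x=False`).

## 2. Ploidy calling (`doscomp.ploidy`)

Per chromosome and sample, the median DNA log2 ratio over non-subtelomeric
genes is mapped through half-open windows:

- median < 0.4 → 2 copies (euploid)
- 0.4 ≤ median < 0.7 → 3 copies
- median ≥ 0.7 → 4 copies

The thresholds bracket the theoretical values log2(3/2) ≈ 0.585 and
log2(4/2) = 1. Chromosomes with fewer than 10 informative genes are flagged
low-confidence. Subtelomeric genes are excluded because they are copy-number
labile and would distort the median.

## 3. Pairwise dosage classification (`doscomp.pairwise`)

For a single aneuploid/euploid strain pair, each gene on the amplified
chromosome is classified from its replicate expression ratios `y` and DNA
ratio mean `x̄`:

1. **excluded_repressed** — any replicate `y < −0.6` (strong repression;
   likely regulatory, not dosage, behaviour).
2. **lower_than_expected** — *all* replicates below the gene's cutoff
   `x̄ − m·SD`, where SD is the standard deviation of DNA ratios across
   retained genes on the chromosome (ddof = 1) and `m` the multiplier
   (1 by default; 2 recommended for single-replicate designs).
3. Otherwise, with all replicates at or above the cutoff:
   **excluded_overexpressed** if any replicate exceeds log2 2.5;
   **higher_than_expected** if all replicates are at least log2 1.5 above
   the expected level (the DNA ratio, or 0 when comparing to the euploid);
   **proportionate** otherwise.
4. Genes with replicates on both sides of the cutoff, or without a cutoff
   (off-chromosome, subtelomeric), are **unscored**.

A common-response filter identifies genes moving in the same direction by
more than 0.4 (log2, strict) in at least 3 strains, separating shared
aneuploidy stress responses from chromosome-specific dosage effects.

## 4. Mixture of linear regressions (`doscomp.mlr`)

### Model

For gene g with DNA doses `x` and expression ratios `y` (all observations
across doses and replicates), conditional on class k:

    y_ij = α_g + β_g x_ij + u_g + ε_ij,   ε_ij ~ N(0, σ_e² s_g²)

where `u_g ~ N(0, σ_u²)` is a gene-level offset shared by all observations
(it models coherent shifts from the common euploid reference and per-gene
normalisation error), and `s_g` is a per-gene noise scale (below). The five
classes constrain (α, β):

| class | α | β | interpretation |
|---|---|---|---|
| 1 | 0 | 1 | dosage-proportionate |
| 2a | α_g ~ TN(μ, σ; α<0) | 1 | proportionate, shifted down |
| 2b | α_g ~ TN(μ, σ; α>0) | 1 | proportionate, shifted up |
| 3a | α_g ~ N(μ, σ) | β_g ~ TN(μ, σ; β<1) | dosage-compensated |
| 3b | α_g ~ N(μ, σ) | β_g ~ TN(μ, σ; β>1) | super-proportionate |

TN denotes a one-sided truncated normal. Random effects are integrated out
analytically: with the compound-symmetry covariance σ²I + τ²J, conjugate
normal algebra plus normal CDF terms give closed-form marginal likelihoods
for every class (verified against adaptive quadrature to 1e-6 relative
error; see the evaluation suite).

### Per-gene noise scales

`s_g` is a moderated estimate: the within-dose replicate variance is pooled
with a chi-squared prior (4 degrees of freedom) toward the median across
genes, then median-normalised so that σ_e remains interpretable. A shared
variance mode (`variance_mode="shared"`, s_g ≡ 1) is available and is used
automatically when dose/replicate structure is absent.

### Fitting

Parameters (mixture weights π, σ_e, σ_u, and the class effect means/SDs) are
estimated by EM:

- **E-step**: posterior class responsibilities from the closed-form
  marginals.
- **M-step**: π in closed form; the remaining 14 parameters by L-BFGS-B on
  the responsibility-weighted expected log-likelihood, with SDs optimised on
  the log scale and truncated-normal means bounded inside their constraint
  regions (e.g. μ_β for class 3a ≤ 0.99) to avoid boundary-hugging
  degenerate optima.

Multiple restarts (OLS-seeded plus jittered) guard against local optima; the
best log-likelihood wins. The likelihood trace is retained and is
non-decreasing up to 1e-9 numerical slack (asserted by the evaluation
suite). Genes are assigned to the posterior-argmax class.

### Nonlinear pre-filter

Before mixture fitting, a likelihood-ratio test compares the per-gene linear
fit against a saturated per-dose-mean model (χ² with doses − 2 df). Genes
with p < threshold are set aside as "nonlinear" (e.g. expression that
saturates or kinks at high dose) since they fit no linear class. Genes with
fewer than 3 distinct doses are exempt.

### Trans responders

For background (unamplified) genes, a per-gene OLS slope of `y` on the
amplified chromosome's dose `x` is tested (t-test on the slope) and
corrected by Benjamini–Hochberg at FDR 0.05 to find genes responding in
trans to the aneuploidy.

## 5. Buffering score (`doscomp.buffering`)

From array-CGH style abundance profiles over a strain panel:

- **Amplification calls**: fold-change ≥ 1.6 relative to the reference.
- **Deduplication**: strains with pairwise profile correlation r > 0.9 are
  grouped by connected components and one representative kept per group.
- **Similarity weights**: each strain is down-weighted by the number of
  similar strains, `w_i = 1 / (1 + Σ_j max(0, (r_ij − 0.4)/0.6))`, so clades
  of related strains do not dominate.
- **Constraint ratio**: `V_g/V_m` per gene, the ratio of expression variance
  across wild strains to variance across mutation-accumulation lines —
  low values indicate selective constraint.
- **Buffering score**: `B_v(g) = Σ_i w_i · amplified[i, g] / (V_g/V_m)_g`.
  High B_v marks genes frequently amplified in nature yet tightly
  constrained in expression, i.e. candidates for dosage buffering.

Group comparisons (e.g. constrained vs background gene sets) use
Mann–Whitney U on log2 V_g/V_m or log2 B_v, or a two-proportion z-test on
copy-number-variable fractions.

## 6. Synthetic data generator (`doscomp.simulate`)

The generator exists to exercise and validate the estimators; its scope is
deliberately limited to the structures the estimators model.

- **`simulate_panel`** — full count-level pipeline: per-class (α, β) effects
  drawn from the truncated-normal laws above, expression built on log2 copy
  dose, negative-binomial-like count noise for mRNA and DNA, replicate
  structure, background chromosomes, and a truth table. A deterministic mode
  (all noise parameters 0) produces exactly reconstructible ratios for
  pipeline identity tests.
- **`simulate_ratio_panel`** — ratio-level panel with exact doses
  x ∈ {0, log2 1.5, 1} and y = α + βx + N(0, residual_sd); "nonlinear" genes
  are flat with a kink at the top dose. This matches the mixture model's
  sampling assumptions exactly and is the substrate for estimator-recovery
  benchmarks: the count-level pipeline adds roughly 0.16 log2 units of
  additional technical noise beyond the nominal residual SD, which is a
  property of the generator's measurement layer, not of the estimator.
- **`simulate_acgh`** — strain × gene abundance profiles with optional clade
  correlation structure and planted amplifications.
- **`simulate_variance_tables`** — wild/MA expression tables with group-wise
  coupling of V_g/V_m for constraint analyses.

All generators are seeded and bit-reproducible.

## 7. Numerical choices

- Marginal likelihoods are computed in log space throughout; mixture sums
  use log-sum-exp. Truncated-normal tail masses use `scipy.stats.norm`
  log-CDF/SF to stay stable far into the tails.
- The compound-symmetry determinant and quadratic form use the rank-one
  update identities rather than explicit matrices, so per-gene cost is
  O(observations).
- EM convergence: relative log-likelihood change < 1e-8, max 200 iterations;
  an increase check raises if the likelihood ever drops by more than 1e-6
  (slack for the inexact generalized M-step).
- BH correction is implemented via `statsmodels.stats.multitest`.

## 8. Limitations

- The mixture model assumes normal log-ratio noise; heavy-tailed count
  artifacts at very low expression are only partially absorbed by the
  moderated per-gene scales and the pre-filter.
- Class labels are identified by their constraint regions; genes with true
  effects very close to a boundary (e.g. β ≈ 1) are intrinsically ambiguous
  and posterior mass splits across neighbouring classes.
- Ploidy windows assume a diploid base and near-complete chromosome
  aneuploidy; segmental events produce intermediate medians and may be
  flagged only through low-confidence gene counts.
- The buffering score inherits the noise of V_g/V_m, which is undefined for
  genes with too few observations or zero MA variance; such genes are
  reported as undefined rather than imputed.
- B_v weighting reduces, but cannot eliminate, phylogenetic
  pseudo-replication in strongly structured strain panels.
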