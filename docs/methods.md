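# Methods

This note documents the statistical models behind `invpap`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Abundance model and preprocessing

The substrate is a proteins × samples matrix of label-free (iBAQ-style)
intensities with missing values. Preprocessing follows the conventions
of label-free proteomics:

* **Presence filter.** A protein is retained when present in at least
  `min_presence_fraction` (default 0.20) of all samples. The comparison
  is inclusive on the exact fraction — 2 of 10 passes a 0.20 threshold,
  6 of 31 (≈0.194) does not — with no rounding of counts. The filter is
  idempotent and order-preserving.
* **Transformation and normalization.** log2, then per-sample median
  centering of present values (default; `none` available). Median
  centering removes sample-loading differences; the median of every
  column is exactly 0 afterwards.
* **Imputation.** Missingness in this data type is left-censored
  (low-abundance values drop out preferentially), so missing cells are
  drawn per sample column from
  `Normal(mean − downshift·SD, (width·SD)²)` with `width = 0.3` and
  `downshift = 1.8` column SDs — the de-facto convention of desktop
  proteomics software. Both parameters are configurable and `none` is
  allowed; columns with fewer than two present values fall back to
  global statistics with a warning. Present values are never altered,
  and the draw is reproducible under the configured seed.
* **PCA.** Samples are embedded on the principal components of the
  complete (imputed) matrix; explained-variance fractions are
  non-increasing and sum to ≤ 1.

## Permutation inference and FDR

Both the two-group Welch statistic (with an optional additive
moderation constant `s0` in the standard-error denominator, default 0)
and the one-way F statistic are referred to a permutation null: sample
labels are permuted jointly across groups, preserving group sizes, and
the same permutation set is reused for every protein in a round
(row-wise exchangeability). Defaults: 1,000 permutations, FDR level
0.05. The permutation count and `s0` are not dictated by any external
convention here; 1,000 rounds put the p-value floor at ~10⁻³, adequate
for a 0.05 FDR decision at this cohort size.

* **p-values** use the add-one rule, `p = (1 + #{|t*| ≥ |t|})/(1 + B)`,
  so they are never zero and remain valid under the null. Permuted
  statistics within 10⁻⁹ of the observed one count as exceedances; this
  guards against summation-order float noise when a permutation
  recreates the original grouping.
* **q-values.** At each |statistic| threshold the estimated
  false-positive count is the **mean** over permutation rounds of the
  number of permuted statistics at or above the threshold, divided by
  the number of observed calls, then made monotone in |statistic| and
  clipped to [0, 1]. The median-count variant was evaluated and
  rejected: the top observed statistic exceeds the permuted maximum in
  about half of all global-null datasets, so the median estimate is 0
  and the protein is called at q = 0 — a structural anticonservative
  failure (measured mean false-discovery proportion 0.40 at q < 0.05 on
  global-null matrices, versus ≤ 0.10 required and observed with the
  mean). No π₀ correction is applied; the estimator is deliberately
  conservative.

With `s0 = 0` and many permutations the two-group p-value converges on
the exact permutation distribution, verified against full enumeration
for 3-vs-3 groups.

## Signature partition

The intermediate phenotype's risk structure is operationalized as a
post-hoc significance pattern on ANOVA-significant proteins, using the
same permutation machinery and FDR level: *NU-like* ⇔ IUP-vs-NU
non-significant AND IUP-vs-PUC significant; *PUC-like* ⇔ the reverse;
up/down by the sign of mean(IUP) − mean(dissimilar group). Proteins
matching neither pattern stay `unassigned` — counts are conservative
rather than forced to a nearest pattern. Swapping the PUC and NU labels
swaps the NU-like and PUC-like classes exactly. Top-k reporting per
class orders by ascending ANOVA q, then descending |F|, then protein id.

## Kernel RFE and panel selection

An RBF-kernel maximum-margin classifier has no primal weight vector, so
the per-feature elimination score is the change in the kernel-space
margin objective `W² = Σᵢⱼ αᵢαⱼyᵢyⱼK(xᵢ,xⱼ)` when the feature is
removed from the kernel with dual coefficients held fixed (for an RBF
kernel, removing feature f multiplies each kernel entry by
`exp(γ(x_if − x_jf)²)`, so all scores of a round cost one fit). The
lowest-scoring 10% of remaining features (minimum one) leave per round;
exactly tied scores leave together, so duplicated columns receive
adjacent ranks.

Two numerical choices matter:

* **Kernel width.** γ is computed once from the full standardized
  feature set (`1/(p·Var)`) and held fixed through the elimination.
  Re-deriving γ per round (the `scale` heuristic) makes the kernel
  sharper as panels shrink, which overfits noise features and buries the
  second of two redundant informative features; with fixed γ both
  planted separating features stay in the top ranks and separable data
  reaches zero cross-validated error.
* **Cross-validation.** Stratified k-fold (default 5; reduced with a
  warning when the smaller class is below k), with features
  standardized inside each training fold only. The chosen panel is the
  smallest size attaining the minimum of the error curve. On strongly
  separable data this is legitimately a panel of one; the shortlist
  then returns the whole panel with a warning.

The shortlist combines the elimination order and the t-test q-value
order as an unweighted rank sum (ties by q, then id).

## Immunoscore and concordance screen

Per antibody, staining-level proportions are scored
`4·p_high + 3·p_medium + 2·p_low + 1·p_not_detected`; multiple
antibodies are averaged, giving a value in [1, 4]. "Relatively
overexpressed in carcinoma" is operationalized as immunoscore ≥ 2.5
(the midpoint; configurable). A candidate is excluded exactly when the
atlas calls it highly expressed in carcinoma while the proteomic fold
change says it is higher in IUP (log2 FC > 0 with the
positive-means-higher-in-IUP convention). Candidates without a score or
fold change are retained as `unscreenable` with a warning, so missing
atlas coverage never silently removes a biomarker. Profiles come from a
local TSV snapshot; nothing is fetched at run time.

## IHC validation statistics

* **H-score** `1·(%1+) + 2·(%2+) + 3·(%3+)` with 0-intensity cells in
  the denominator; range [0, 300]; a merged specimen's score is the
  cell-count-weighted mean of its parts.
* **Mann–Whitney**: exact distribution when the smaller group has ≤ 8
  observations without ties, otherwise the tie-corrected normal
  approximation with continuity correction (scipy).
* **AUROC** is the Mann–Whitney estimator (ties ½), tested against 0.5
  with the Hanley–McNeil standard error (DeLong optional); at perfect
  separation the observed SE degenerates to 0 and the null-variance SE
  is substituted so the p-value stays defined.
* **Youden cutoff**: thresholds are midpoints between adjacent distinct
  scores; the maximizer of sensitivity + specificity − 1 wins, ties to
  the lower threshold; the direction flag (positives score higher, the
  default) is exposed because cutoff conventions differ between tools.
* **Clopper–Pearson** exact intervals from beta quantiles, returned in
  percent unrounded; rounding (1 decimal) happens only at presentation.

## Survival screening

Univariate Cox proportional hazards on continuous log2 expression
(lifelines, Efron tie handling — the modern default), hazard ratio per
expression doubling with 95% Wald CI; and a median-split Kaplan–Meier
comparison with the log-rank test, ties at the median going to the low
group (documented because expression medians tie frequently on real
data). For a binary covariate without tied event times the Cox score
test at β = 0 coincides with the log-rank statistic; the test suite
verifies this identity numerically.

## Synthetic cohorts: what they emulate, and what they don't

The generators reproduce the *statistical shape* of the study:

* **Discovery proteome**: 9/12/10 samples, 5,000 proteins, baseline
  log2 intensities `N(25, 2²)` (≈ the iBAQ dynamic range), 40 planted
  proteins per signature class shifted by 2.0 log2 units in their class
  pattern, residual noise SD 0.5, and *intensity-dependent* dropout:
  everything below each sample's 20% intensity quantile goes missing.
  MNAR (not MCAR) dropout was chosen deliberately so the imputation
  path is exercised the way real label-free data exercises it.
* **IHC cohort**: 25 + 16 specimens, 500 cells each, per-cell intensity
  bins drawn multinomially from diagnosis-specific probability vectors
  (expected H-score `100(p₁ + 2p₂ + 3p₃)` in closed form). An optional
  per-specimen Dirichlet jitter (off by default, used in the analysis
  narrative at concentration 15) adds between-patient staining
  heterogeneity so H-score distributions overlap realistically.
* **Survival cohort**: 405 patients, expression ~ N(0,1) per gene,
  exponential event times with hazard `λ₀·exp(Σβx)`, λ₀ = ln2/30 (30-
  month median survival), independent uniform censoring with the upper
  bound calibrated on the realized event-time sample to hit the target
  censoring rate (default 50%).
* **Staining profiles**: concordant (weak-staining) or discordant
  (strong-staining) Dirichlet draws paired with planted positive fold
  changes, so the concordance screen's exclusions are predictable.

Passing tests on these cohorts show that each stage recovers what was
planted under the stated noise model. They do **not** show that the
original study's headline numbers are reproduced: the quantified
protein counts, DEP count, signature sizes, SVM error rates, AUROC,
H-score cutoff and TCGA hazard ratios all depend on the original
MS/IHC/TCGA measurements, which this package does not consume. Planted
effects are additive Gaussian on log2 scale; real proteomes have
correlated proteins, batch structure and heavier tails, none of which
are modelled.

## Problem sizes in the test suite

The default suite runs the study's group sizes everywhere but scales
protein counts to keep the feedback loop tight: FDR calibration uses
500-protein null matrices over 20 seeds; signature recovery uses 1,000
proteins with the full 160 planted markers; feature-selection recovery
uses the 50-feature/2-planted design over 10 seeds; Cox recovery uses
the full 405-patient cohort over 20 seeds. The analysis scripts run the
full 5,000-protein proteome. Signature recovery is scored over planted
proteins that pass the presence filter: under MNAR dropout a small
fraction of planted proteins (≈9% at the default settings) never enter
the quantified matrix, and no assignment rule can reach them.

## Known limitations

* The FDR estimator is π₀-free and hence conservative when many
  proteins are truly differential.
* The RFE importance score holds dual coefficients fixed on removal — a
  first-order approximation; fully retraining per candidate removal
  would be quadratic in the panel size.
* The Hanley–McNeil AUC test assumes the binormal-ish variance
  approximation; for very small or very unbalanced cohorts the DeLong
  option is preferable.
* Cox fitting inherits lifelines' behaviour under monotone likelihood
  (separation): coefficients are flagged by lifelines' own warnings
  rather than silently truncated.
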