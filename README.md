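# invpap

Proteomic biomarker discovery for distinguishing **inverted urothelial
papilloma (IUP)** — a benign bladder neoplasm — from **papillary
urothelial carcinoma (PUC) with inverted growth**, its histologic mimic.
The package implements the complete discovery-to-validation workflow as
a tested, reusable pipeline and exercises it end-to-end on synthetic
cohorts with recorded ground truth, for pathologists and computational
biologists who want to audit, reuse or extend each statistical step.

## The workflow

Given a label-free (iBAQ-style) protein abundance matrix over three
tissue groups (9 IUP / 12 PUC / 10 normal urothelium, NU):

1. **Preprocessing** — keep proteins quantified in ≥20% of samples,
   log2-transform, median-center each sample, impute left-censored
   missing values from a downshifted normal
   (N(μ − 1.8σ, (0.3σ)²) per sample column), PCA embedding.
2. **Differential expression** — Welch-type t statistic (optional `s0`
   moderation) and one-way F statistic with *permutation* inference:
   two-sided p = (1 + #{|t*| ≥ |t|}) / (1 + B), and FDR q-values from
   the mean permuted exceedance count per |statistic| threshold,
   enforced monotone. A protein is a DEP when q < 0.05.
3. **Signature partition** — each ANOVA-significant protein is post-hoc
   tested IUP-vs-NU and IUP-vs-PUC; IUP≈NU & IUP≠PUC ⇒ *NU-like*
   (low-risk), the reverse ⇒ *PUC-like* (high-risk); up/down by the sign
   of the IUP − dissimilar-group mean difference.
4. **SVM-RFE panel selection** — recursive feature elimination around an
   RBF-kernel SVM; feature f is scored by |ΔW²| where
   W² = ΣᵢⱼαᵢαⱼyᵢyⱼK(xᵢ,xⱼ) with f removed from the kernel; the
   stratified cross-validated error curve picks the smallest panel at
   minimum error; the shortlist ranks panel members by
   (ML rank + t-test-FDR rank).
5. **Immunoscore concordance screen** — antibody staining profiles are
   scored 4·p_high + 3·p_medium + 2·p_low + 1·p_nd (averaged over
   antibodies, range 1–4); candidates called highly expressed in
   carcinoma by the atlas (score ≥ 2.5) but *down* in carcinoma in the
   proteome are excluded.
6. **IHC validation** — per-specimen H-score
   `1·(% cells 1+) + 2·(% cells 2+) + 3·(% cells 3+)` ∈ [0, 300],
   Mann–Whitney comparison, AUROC (Mann–Whitney estimator,
   Hanley–McNeil test vs 0.5), Youden-optimal cutoff, Clopper–Pearson
   exact 95% CIs for sensitivity/specificity.
7. **Survival screen** — univariate Cox proportional hazards on log2
   expression (Efron ties, Wald CI) and median-split Kaplan–Meier with
   the log-rank test, on a 405-patient cohort.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts (outputs land in `results/`):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_preprocess_and_pca.py
python analysis/03_differential_expression.py
python analysis/04_signature_partition.py
python analysis/05_feature_selection.py
python analysis/06_hpa_concordance_screen.py
python analysis/07_ihc_validation.py
python analysis/08_survival_screen.py
```

Output of one full run (seed 20260929):

```
discovery proteome: 5000 proteins x 31 samples, 20.0% missing, planted 160 markers
presence filter (>= 20% of samples): 4291 of 5000 proteins retained
ANOVA: 136 DEPs of 4291 proteins at q < 0.05
NU_like_up: 38 proteins ... PUC_like_down: 30 proteins
ground-truth recovery among analyzable planted markers: 94.3%
minimum CV error 0.0% reached at panel size 1 (of 4291 proteins)
10 of the top 10 ranked proteins are planted markers
P00050: immunoscore 1.60, log2 FC -2.47 -> retained_concordant
AUROC 1.000 (p = 9.03e-08 vs 0.5); cutoff H-score 54.3
sensitivity 100% (95% CI 86.3-100.0%), specificity 100% (95% CI 79.4-100.0%)
PYGB_like: HR 1.406 (95% CI 1.226-1.614), Cox p = 0.0000 *
```

Reading this: of the 160 planted markers, 94% of those surviving the
presence filter are assigned their true signature class; the SVM-RFE
ranking puts planted IUP-vs-PUC discriminators in all top-10 positions,
and because the planted effect (2 log2 units at SD 0.5) makes the
classes separable, a single protein already achieves zero
cross-validated error, so the smallest-panel rule selects it. The IHC
cohort (25 vs 16 specimens) separates perfectly at an H-score cutoff of
54.3, and the survival screen recovers the two genes simulated with
nonzero log hazard ratios while leaving the four null genes
non-significant.

The same workflow runs as a single configured command on any input
bundle:

```bash
invpap simulate --seed 7 --out inputs/        # or bring your own TSVs
invpap run --config run.yaml      # see docs/run.example.yaml
```

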