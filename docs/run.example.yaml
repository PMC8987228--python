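# Example configuration for `invpap run --config run.yaml`.
# Generate a matching input bundle with: invpap simulate --seed 3 --out inputs
abundance_path: inputs/abundance.tsv
metadata_path: inputs/metadata.tsv
hpa_profiles_path: inputs/hpa_profiles.tsv   # optional
ihc_cells_path: inputs/ihc_cells.csv         # optional
survival_path: inputs/survival.tsv           # optional
survival_genes: [GENE_A]
out_dir: out
seed: 3
cv_folds: 5
hpa_cutoff: 2.5
shortlist_k: 5
preprocess:
  min_presence_fraction: 0.20
  normalization: median-center
  imputation: downshifted-normal
  impute_width: 0.3
  impute_downshift: 1.8
  seed: 3
permutation:
  n_permutations: 1000
  s0: 0.0
  fdr_level: 0.05
  seed: 3
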