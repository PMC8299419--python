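# Eight-dataset synthetic reproduction: five tissues, both sexes, one
# proteomics set; two universal planted longevity genes (|rho| = 0.95)
# with tissue-specific signs over 500 background features per dataset.
# The two liver datasets use the whole strain panel instead of the
# extreme tails (they are the sparsely profiled tissue in this design).
out_dir: results/reproduction
seed: 1
thresholds: [0.4, 0.7]
synthetic:
  seed: 1
  n_strains: 60
  strains_per_dataset: 43
  n_datasets: 8
  n_features_per_dataset: 500
  default_planted: true
selection_mode_overrides:
  d5_liver_female_transcript: all
  d6_liver_female_protein: all
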