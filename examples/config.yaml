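# Example pipeline configuration for `omicbv run-all`.
# Any omitted key falls back to the library default.
synthetic:
  n_transcripts: 1000
  n_snps: 2000
  n_causal_snps: 40
  n_signal_transcripts: 100
  seed: 1
run:
  theta: 1.0
  min_mean_log2: 3.0
  lfdr_cutoff: 0.05
  prune_r_cutoff: 0.5
  transcript_phen_r_cutoff: 0.05
  snp_phen_alpha: 0.05
  relative_variance_cutoff: 1.0
  n_bootstrap: 25
  seed: 1
split:
  train_batches: ["1"]
  test_batches: ["2", "3"]
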