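# Fully synthetic demonstration design: four gene groups (activation,
# migration, mixed, null), two timepoints, three replicates with library
# sizes 1, 2 and 4 million reads.
seed: 1
simulate:
  n_genes_per_scenario: 50
  timepoints: [t0, t1]
  library_sizes: [1.0, 2.0, 4.0]
  noise_mode: poisson
contrast:
  condition_a: t1
  condition_b: t0
  lfc_thresh: 1.0
  fdr_thresh: 0.1
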