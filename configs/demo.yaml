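# End-to-end demo: a scaled-down study with planted ground truth.
# The pipeline recovers the planted 20-gene core signature exactly.
out_dir: results/demo
permutation_b: 199
fdr_target: 0.10
simulation:
  seed: 1
  n_genes: 200
  bound_fraction: 0.25
  binding_shift: 1.5
  noise_sd: 0.3
  de_fraction: 0.10
  de_log2fc: 2.0
  monotone_fraction_bg: 0.10
  compendium:
    n_samples: 600
    n_celltypes: 30
    signature_size: 20
    n_enriched_celltypes: 3
    target_r: 0.47
    tumor_fraction: 0.577
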