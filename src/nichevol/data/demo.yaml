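# Demo configuration: a small two-domain survey that exercises every
# pipeline stage in a few minutes on one CPU.
seed: 1
outdir: nichevol_demo
synth:
  n_taxa: 150
  depth: 3000
  replicates: 3
synth_euk:
  n_taxa: 80
  depth: 3000
  replicates: 3
preprocess:
  min_reads: 10
niche:
  n_perm: 300
  scheme: swap
assembly:
  n_null: 199
  max_pairs: 120
network:
  r_min: 0.6
  alpha: 0.05
  n_bootstrap: 50
  n_random: 50
  min_reads: 50
stability:
  fraction: 0.5
  reps: 100
evo:
  n_tips: 100
  lambda_g: 1.0
  lambda_s: 2.0
  mu_g: 0.2
  mu_s: 0.2
  t_gs: 0.2
  t_sg: 0.1
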