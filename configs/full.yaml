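ai_obs_limit: 1000
chromosome_lengths:
- 100.0
- 100.0
- 100.0
- 100.0
- 100.0
gamma_scale: 5.4
gamma_shape: 0.84
genomic_reml_method: auto
heritabilities:
- 0.3
- 0.05
hist_dams: 50
hist_generations: 50
hist_sires: 50
marker_spacing: 0.1
masking_fraction: 0.9
mme_exact_limit: 60000
n_dams: 200000
n_eval_generations: 4
n_qtl: 300
n_sires: 1000
pedigree_reml_method: auto
qtl_group_sizes: null
reliability_variant: pev
replicates: 10
ridge: 1.0e-06
scenario: no_missing
seed: 0
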