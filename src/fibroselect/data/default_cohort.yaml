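n_tif_test: 42
n_notif_test: 34
n_healthy_test: 14
n_tif_val: 28
n_notif_val: 21
n_healthy_val: 8
noise_sd: 1.0
gene_corr: 0.2
informative_tif_genes: null
informative_gs_genes: null
gs_grade_slope: 0.45
gs_noise_sd: 0.7
healthy_offset: 0.0
scr_log_intercept: 4.143134726391533
scr_log_slope: 0.27
scr_log_sd: 0.4
egfr_intercept: 106.0
egfr_slope: -18.4
egfr_sd: 26.0
protein_log_intercept: 0.1823215567939546
protein_log_slope: 0.25
protein_log_sd: 1.0
seed: 0
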