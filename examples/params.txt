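# metaboqc parameter file: key=value, one per line
feature_missingness_max=0.2
sample_missingness_max=0.2
tsa_sd_threshold=5
outlier_iqr_multiplier=5
pca_outlier_mode=leave
tree_cut_height=0.5
pc_sd_threshold=5
exclude_derived=TRUE
batch_normalization_column=batch
rng_seed=1234
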