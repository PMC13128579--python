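# Default preprocessing for single-cell (checkpoint-driven) scoring.
# In this mode the gene universe is frozen in the checkpoint, so HVG
# selection is bypassed (gene_selection_method: all) and clone collapsing
# is unused unless clonotypes are supplied.
min_cell_fraction: 0.10
n_hvg: 5000
exclusion_patterns: ["MT-", "RPL", "RPS", "LINC", "MALAT1"]
n_bins: 20
transform: expression_binning
collapse_percentile: 75
gene_selection_method: all
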