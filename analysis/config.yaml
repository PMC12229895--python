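# Thresholds used by the numbered analysis drivers; defaults mirror the
# study's printed constants. See src/ablmap/config.py for the full list.
alpha: 0.05
high_corr_threshold: 0.7
reference_corr_threshold: 0.6
exclusion_radius_um: 15.0
baseline_days: [1, 3, 5]
n_perm: 200
n_shuffle: 500
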