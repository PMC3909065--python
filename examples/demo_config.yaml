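# Demo pipeline configuration; run with:
#   circmir all --config examples/demo_config.yaml --out results/demo
# A scaled-down end-to-end run (screen -> rank -> qpcr -> associate -> panel)
# that finishes in well under a minute.
seed: 5
n_probes: 40
n_planted: 4
delta_ct_shift: 2.0            # screen effect: ~2-SD class separation
validation_delta_ct_shift: 0.52  # validation effect: single-miRNA AUC ~0.68
n_repeats: 15
top_k: 8
n_validation_cases: 44
n_validation_controls: 46
max_panel_size: 3
log_level: WARNING
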