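# Demo pipeline profile: 4 postnatal days x 12 desk-scale phantoms.
# Runs in well under a minute on one CPU core.
voxel_size_um: 1.48
n_acini_per_day: 12
n_alveoli_render: 8
noise_sd: 0.0
slice_interval: 4
grid_spacing_vox: 4
subsample_denominator: 3
seed: 7
outdir: pipeline_out
make_figures: false
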