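# Minimal end-to-end pipeline configuration: 16 small wells, a reduced
# two-scale model, two training epochs. Finishes in well under a minute.
sim:
  fov_size: 128
  mean_cells: 40
  sd_cells: 5
  nucleus_radius_range: [4, 7]
plate_size: 4
design:
  - gene: KRAS
    variant: WT
    annotation_class: WT
    n_wells: 8
    alpha: 0.05
  - gene: KRAS
    variant: G12V
    annotation_class: activating
    n_wells: 8
    alpha: 0.9
split:
  fractions: [0.6, 0.2, 0.2]
model:
  scales: [128, 64]
  patch: 64
  filters: [4, 8, 16, 32]
  fc_widths: [32, 32]
  dropout: 0.1
train:
  batch_size: 8
  learning_rate: 0.001
  max_epochs: 2
  early_stop_patience: 2
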