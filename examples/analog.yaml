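# The scaled-down synthetic benchmark: 160 wells at 512 px, reduced cell
# density, wildtype-like vs activating arms over 16 plates, trained with
# the published recipe (batch 32, Adam 1e-4, early stopping).
sim:
  fov_size: 512
  mean_cells: 500
  sd_cells: 100
plate_size: 10
design:
  - gene: KRAS
    variant: WT
    annotation_class: WT
    n_wells: 80
    alpha: 0.05
  - gene: KRAS
    variant: G12V
    annotation_class: activating
    n_wells: 80
    alpha: 0.9
split:
  fractions: [0.6, 0.2, 0.2]
model:
  scales: [512, 256, 128]
  patch: 128
train:
  batch_size: 32
  learning_rate: 0.0001
  max_epochs: 25
  early_stop_patience: 5
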