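# pathscore

Scoring pathway activation of gene variants from fluorescence well
images with a multi-scale convolutional network — plus a calibrated
synthetic translocation-assay simulator that makes the whole pipeline
testable end-to-end without any proprietary data.

## The problem

Most tumors carry *variants of uncertain significance* (VUS): gene
alterations with no published functional evidence. A scalable way to
classify them is a functional imaging assay: cells are co-transfected
with the tested variant (mCherry-tagged) and a fluorescent reporter
(GFP-tagged ERK2 or STAT3) that translocates from cytoplasm to nucleus
when the variant activates its signaling pathway; nuclei are DAPI
stained. Each well yields a three-channel field of view with thousands
of cells, ~12% of them transfected. The task is to turn one such image
into a pathway-activation score, aggregate scores per variant, call
variants active or benign, and read out drug dose-response curves.

`pathscore` implements that computational system for people building or
evaluating image-based variant-function assays:

* **`pathscore.simdata`** — synthetic plates with known ground truth,
  calibrated to the assay's field statistics (3,543 ± 767 nuclei per
  field, ~12% transfected; reporter redistributed by a latent activation
  level α with per-cell total signal conserved).
* **`pathscore.model`** — the multi-scale network: image pyramid (1024²,
  512², 256²) → 256² patches (16 + 4 + 1 = 21) → five conv–ReLU–batchnorm
  –maxpool modules with filters (4, 8, 16, 32, 64) → 8×8×64 block →
  global average pooling (|V| = 64) → concatenated 1344-d embedding →
  three 100-unit FC layers with 20% dropout → one sigmoid unit (or a
  7-way gene-identity softmax). 229,681 parameters; implemented on
  NumPy + numba with explicit backprop, trainable on one CPU core.
* **`pathscore.dataio`** — TIFF/CSV manifests and plate-stratified
  60/20/20 splits (plates never straddle splits).
* **`pathscore.training`** — batch 32, Adam 1e-4, early stopping on
  validation loss, best-epoch checkpointing, plate-leakage audit.
* **`pathscore.scoring`** — per-image scores, per-variant mean ± SEM
  with the strict 0.5 activity call, per-class breakdown tables,
  per-residue position profiles, Welch t-test against wildtype.
* **`pathscore.doseresponse`** — mean-score-per-concentration series
  with SEM, potency ordering, high-dose rebound detection.
* **`pathscore.evaluation`** — ROC/AUC, accuracy, binary and multi-class
  confusion matrices, and a non-learned nuclear:cytoplasmic intensity
  oracle (Otsu + watershed segmentation) for independent validation.

## Worked example

Run the whole pipeline — simulate, split, train, score, evaluate — from
one config:

```bash
pathscore run --config examples/smoke.yaml --out runs/smoke --seed 5
```

or drive it from Python:

```python
import tempfile
from pathscore.dataio import Dataset, SplitSpec, split_by_plate
from pathscore.evaluation import accuracy, roc_auc
from pathscore.model import ModelSpec
from pathscore.scoring import score_dataset
from pathscore.simdata import DesignItem, SimParams, generate_experiment
from pathscore.training import TrainConfig, train

params = SimParams(fov_size=512, mean_cells=500, sd_cells=100)
design = [
    DesignItem("KRAS", "WT", "WT", 60, alpha=0.05),
    DesignItem("KRAS", "G12V", "activating", 60, alpha=0.9),
]
out = tempfile.mkdtemp()
manifest = generate_experiment(design, params, out, seed=1, plate_size=10)
dataset = Dataset(manifest, out)
parts = split_by_plate(dataset, SplitSpec((0.6, 0.2, 0.2), seed=1))

spec = ModelSpec(scales=(512, 256, 128), patch=128)
net, history = train(spec, parts[0], parts[1],
                     TrainConfig(batch_size=32, learning_rate=1e-4,
                                 max_epochs=42, early_stop_patience=6,
                                 seed=1))
scored = score_dataset(net, parts[2])           # held-out plates only
labels = (scored.annotation_class != "WT").astype(int)
print("held-out AUC:", roc_auc(scored.score, labels)[0])
print("held-out accuracy:", accuracy(scored.score, labels))
print(scored.groupby("variant").score.mean())
```

Output (seed 1; about ten minutes on one CPU core):

```
held-out AUC: 1.0
held-out accuracy: 1.0
variant
G12V    0.993764
WT      0.011153
Name: score, dtype: float64
```

The two arms separate completely on plates the model never saw: every
activating well scores far above the 0.5 sigmoid midpoint and every
wildtype-like well far below it.

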