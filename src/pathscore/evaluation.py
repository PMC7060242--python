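"""Performance surfaces (ROC/AUC, accuracy, confusion matrices) and an
independent, non-learned translocation readout.

The classical oracle segments nuclei from the nuclear-stain channel,
gates transfected cells on the marker channel, and reports the median
nuclear-to-perinuclear reporter intensity ratio. It shares no code or
parameters with the network, which makes it useful both for validating
the simulator and as a sanity benchmark for the learned score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve

from .exceptions import DataError
from .types import WellImage


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(scores, labels):
    """Empirical ROC by trapezoidal rule; returns (auc, fpr, tpr, thresholds).

    Equals the probability that a random positive outranks a random
    negative, counting ties as one half (mid-rank convention).
    """
    y = np.asarray(labels).astype(int).ravel()
    s = np.asarray(scores, float).ravel()
    if y.min() == y.max():
        raise DataError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, s)
    return float(np.trapezoid(tpr, fpr)), fpr, tpr, thr


def pairwise_auc(scores, labels) -> float:
    """Brute-force AUC: fraction of positive-negative pairs ranked correctly
    (ties count 1/2). Quadratic; intended as an oracle for small inputs."""
    s = np.asarray(scores, float).ravel()
    y = np.asarray(labels).astype(int).ravel()
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("AUC needs both classes present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    """Fraction of correct calls at a score threshold (strict >)."""
    y = np.asarray(labels).astype(int).ravel()
    pred = (np.asarray(scores, float).ravel() > threshold).astype(int)
    return float((pred == y).mean())


# ---------------------------------------------------------------------------
# confusion matrices

def binary_confusion(scores, labels, threshold: float = 0.5) -> pd.DataFrame:
    """2x2 count matrix (rows: true class, columns: predicted class)."""
    y = np.asarray(labels).astype(int).ravel()
    pred = (np.asarray(scores, float).ravel() > threshold).astype(int)
    m = _sk_confusion(y, pred, labels=[0, 1])
    return pd.DataFrame(m, index=["true_WT", "true_mutant"],
                        columns=["pred_WT", "pred_mutant"])


def gene_confusion(probs, onehot, genes):
    """Multi-class confusion by argmax (ties -> lowest gene index).

    Returns (count matrix, row-percentage matrix) as DataFrames.
    """
    p = np.asarray(probs, float)
    y_true = np.asarray(onehot).argmax(axis=1)
    y_pred = p.argmax(axis=1)
    m = _sk_confusion(y_true, y_pred, labels=list(range(len(genes))))
    counts = pd.DataFrame(m, index=genes, columns=genes)
    row_tot = counts.sum(axis=1).replace(0, np.nan)
    percent = counts.div(row_tot, axis=0) * 100.0
    return counts, percent


@dataclass
class EvalReport:
    """Per-gene and aggregate performance of the activation head."""

    per_gene_auc: dict
    per_gene_accuracy: dict
    binary_confusions: dict = field(default_factory=dict)
    gene_confusion_counts: pd.DataFrame | None = None
    gene_confusion_percent: pd.DataFrame | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(list(self.per_gene_auc.values())))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.per_gene_accuracy.values())))

    def to_json(self, path) -> None:
        payload = {
            "per_gene_auc": self.per_gene_auc,
            "mean_auc": self.mean_auc,
            "per_gene_accuracy": self.per_gene_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "binary_confusions": {
                g: df.to_dict() for g, df in self.binary_confusions.items()
            },
        }
        if self.gene_confusion_counts is not None:
            payload["gene_confusion_counts"] = self.gene_confusion_counts.to_dict()
            payload["gene_confusion_percent"] = self.gene_confusion_percent.to_dict()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def build_report(scores, labels, genes_per_image, threshold: float = 0.5) -> EvalReport:
    """Per-gene AUC/accuracy/confusion of binary activation scores.

    ``mean_auc``/``mean_accuracy`` are unweighted means over genes.
    """
    s = np.asarray(scores, float).ravel()
    y = np.asarray(labels).astype(int).ravel()
    g = np.asarray(genes_per_image)
    aucs, accs, confs = {}, {}, {}
    for gene in sorted(set(g)):
        m = g == gene
        aucs[gene] = roc_auc(s[m], y[m])[0]
        accs[gene] = accuracy(s[m], y[m], threshold)
        confs[gene] = binary_confusion(s[m], y[m], threshold)
    return EvalReport(per_gene_auc=aucs, per_gene_accuracy=accs,
                      binary_confusions=confs)


# ---------------------------------------------------------------------------
# classical translocation oracle

@dataclass
class OracleResult:
    """Per-well translocation statistic; ``ratio`` is None for an empty well."""

    ratio: float | None
    n_cells_used: int
    n_nuclei: int

    @property
    def is_empty(self) -> bool:
        return self.ratio is None


def _segment_nuclei(nuclear: np.ndarray, min_distance: int = 5):
    th = threshold_otsu(nuclear) if nuclear.max() > nuclear.min() else np.inf
    mask = nuclear > th
    if not mask.any():
        return np.zeros(nuclear.shape, int), 0
    mask = ndi.binary_fill_holes(mask)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(nuclear.shape, int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)
    return labels, int(labels.max())


def oracle_ratio(image: WellImage, annulus_width: int = 4,
                 min_marker_snr: float = 6.0) -> OracleResult:
    """Median nuclear / perinuclear reporter intensity over transfected cells.

    Nuclei come from Otsu thresholding of the nuclear channel with hole
    filling and watershed splitting; a nucleus counts as transfected when
    its mean marker intensity clears both the Otsu level of the marker
    channel and a robust background floor (median + ``min_marker_snr``
    scaled MADs). Wells with no transfected cell detected yield an
    explicit empty result rather than a number.
    """
    nuclear = image.channel("nuclear")
    marker = image.channel("marker")
    reporter = image.channel("reporter")

    labels, n_nuclei = _segment_nuclei(nuclear)
    if n_nuclei == 0:
        return OracleResult(None, 0, 0)

    med = float(np.median(marker))
    mad = float(np.median(np.abs(marker - med)))
    floor = med + min_marker_snr * 1.4826 * max(mad, 1e-6)
    try:
        gate = max(float(threshold_otsu(marker)), floor)
    except ValueError:
        gate = floor

    all_nuclei = labels > 0
    selem = disk(annulus_width)
    ratios = []
    objects = ndi.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        # widen the bounding box to fit the annulus
        sl_w = tuple(
            slice(max(s.start - annulus_width, 0), min(s.stop + annulus_width, dim))
            for s, dim in zip(sl, labels.shape)
        )
        nuc = labels[sl_w] == lab
        if float(marker[sl_w][nuc].mean()) <= gate:
            continue
        ann = ndi.binary_dilation(nuc, structure=selem) & ~all_nuclei[sl_w]
        if not ann.any():
            continue
        nuc_mean = float(reporter[sl_w][nuc].mean())
        ann_mean = float(reporter[sl_w][ann].mean())
        ratios.append(nuc_mean / max(ann_mean, 1e-6))
    if not ratios:
        return OracleResult(None, 0, n_nuclei)
    return OracleResult(float(np.median(ratios)), len(ratios), n_nuclei)
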