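"""Training loop: Adam on mini-batches, plate-disjointness audit,
validation-loss checkpoint selection and early stopping.

The published training recipe is followed: batch size 32 and Adam with a
learning rate of 1e-4. The stopping rule (not part of the recipe) is
early stopping on validation loss with a small patience. Large batches
are processed in micro-batches with gradient accumulation so peak memory
stays modest; batch normalization normalizes per micro-batch (ghost
batch norm) while its inference statistics are pooled over each full
epoch and adopted before validation (see ``pathscore.nn.BatchNorm2d``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .dataio import Dataset
from .exceptions import ConfigurationError, DataError
from .model import ModelSpec, MultiScaleNet


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-4
    max_epochs: int = 50
    early_stop_patience: int = 5
    seed: int = 0
    augment: bool = False          # random flips / 90-degree rotations
    micro_batch: int = 8           # images per gradient-accumulation slice

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.max_epochs < 1 or self.early_stop_patience < 0:
            raise ConfigurationError("invalid epoch/patience settings")


def binary_labels(dataset: Dataset) -> np.ndarray:
    """WT wells are negatives (0), everything else a positive (1)."""
    cls = dataset.manifest["annotation_class"].astype(str)
    return (cls != "WT").to_numpy(dtype=np.float32)


def gene_labels(dataset: Dataset, genes=None):
    """One-hot gene identity labels; returns (onehot, gene order)."""
    col = dataset.manifest["gene"].astype(str)
    if genes is None:
        genes = sorted(col.unique())
    index = {g: i for i, g in enumerate(genes)}
    unknown = sorted(set(col) - set(genes))
    if unknown:
        raise DataError(f"genes not in label set: {unknown}")
    onehot = np.zeros((len(col), len(genes)), np.float32)
    onehot[np.arange(len(col)), col.map(index).to_numpy()] = 1.0
    return onehot, list(genes)


def _audit_plates(train_ds: Dataset, val_ds: Dataset) -> None:
    overlap = set(train_ds.plate_ids) & set(val_ds.plate_ids)
    if overlap:
        raise DataError(f"plates present in both train and validation: {sorted(overlap)}")


def _augment_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = x.copy()
    for i in range(out.shape[0]):
        k = rng.integers(4)
        if k:
            out[i] = np.rot90(out[i], k, axes=(0, 1))
        if rng.random() < 0.5:
            out[i] = out[i][:, ::-1]
    return out


def _take(x, sel):
    """Index into an image array or a precomputed pyramid (list of arrays)."""
    if isinstance(x, (list, tuple)):
        return [a[sel] for a in x]
    return x[sel]


def _count(x) -> int:
    return x[0].shape[0] if isinstance(x, (list, tuple)) else x.shape[0]


def _forward_loss(net, x, y, train, rng, grad_scale=1.0):
    z = net.forward(x, train=train, rng=rng)
    if net.spec.head == "activation":
        loss, dz = nn.bce_with_logits(z, y)
    else:
        loss, dz = nn.ce_with_logits(z, y)
    if train:
        net.backward(dz * grad_scale)
    return loss


def evaluate_loss(net: MultiScaleNet, x, y: np.ndarray,
                  micro_batch: int = 8) -> float:
    """Mean loss in inference mode (dropout off, BN running statistics)."""
    total, n = 0.0, _count(x)
    for i in range(0, n, micro_batch):
        xb = _take(x, slice(i, i + micro_batch))
        yb = y[i : i + micro_batch]
        total += _forward_loss(net, xb, yb, train=False, rng=None) * _count(xb)
    return total / n


def train(spec: ModelSpec, train_ds: Dataset, val_ds: Dataset,
          config: TrainConfig, labels: str = "binary", genes=None,
          verbose: bool = False):
    """Train a :class:`MultiScaleNet`; returns ``(net, history)``.

    The returned network carries the weights of the epoch with the lowest
    validation loss; ``history`` is a DataFrame with one row per epoch
    (train_loss, val_loss, best flag). Fully reproducible under a fixed
    ``config.seed`` on a fixed BLAS configuration.
    """
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise DataError("empty train or validation split")
    _audit_plates(train_ds, val_ds)

    if labels == "binary":
        if spec.head != "activation":
            raise ConfigurationError("binary labels require the activation head")
        y_train = binary_labels(train_ds)
        y_val = binary_labels(val_ds)
    elif labels == "gene":
        if spec.head != "gene":
            raise ConfigurationError("gene labels require the gene head")
        y_train, gene_order = gene_labels(train_ds, genes)
        y_val, _ = gene_labels(val_ds, gene_order)
        if len(gene_order) != spec.n_genes:
            raise ConfigurationError(
                f"gene head width {spec.n_genes} != {len(gene_order)} genes in data"
            )
    else:
        raise ConfigurationError(f"unknown label mode {labels!r}")

    from .model import make_pyramid

    side = spec.scales[0]
    x_train = train_ds.load_arrays(side)
    x_val = val_ds.load_arrays(side)
    # the pyramid is deterministic per image: cache it across epochs unless
    # augmentation perturbs the raw images each batch
    if not config.augment:
        x_train = make_pyramid(spec, x_train)
    x_val = make_pyramid(spec, x_val)

    rng = np.random.default_rng(config.seed)
    net = MultiScaleNet(spec, seed=int(rng.integers(2**31)))
    opt = nn.Adam(net.param_items(), lr=config.learning_rate)

    n = _count(x_train)
    best_val, best_state, best_epoch = np.inf, None, -1
    rows = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb_full, yb_full = _take(x_train, idx), y_train[idx]
            if config.augment:
                xb_full = _augment_batch(xb_full, rng)
            net.zero_grad()
            batch_loss = 0.0
            for m in range(0, len(idx), config.micro_batch):
                xb = _take(xb_full, slice(m, m + config.micro_batch))
                yb = yb_full[m : m + config.micro_batch]
                # dz from each micro-batch is already divided by its own
                # size; rescale so the whole batch averages correctly
                nb = _count(xb)
                scale = nb / len(idx)
                loss = _forward_loss(net, xb, yb, train=True, rng=rng,
                                     grad_scale=scale)
                batch_loss += loss * nb
            opt.step()
            epoch_loss += batch_loss
            seen += len(idx)
        train_loss = epoch_loss / seen
        net.adopt_bn_stats()  # inference statistics pooled over this epoch
        val_loss = evaluate_loss(net, x_val, y_val, config.micro_batch)
        improved = val_loss < best_val
        if improved:
            best_val, best_state, best_epoch = val_loss, net.copy_state(), epoch
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
             "best": improved}
        )
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}"
                  f"{'  *' if improved else ''}", flush=True)
        if epoch - best_epoch >= config.early_stop_patience:
            break
    net.load_state(best_state)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    history.attrs["best_val_loss"] = best_val
    return net, history
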