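"""Multi-scale patch-based convolutional network for well-image scoring.

The computation path mirrors the assay classifier's design: the input
field of view is rendered at several resolutions (an image pyramid), each
resolution is tiled into fixed-size patches, every patch runs through a
small five-module convolutional feature extractor (conv 3x3 -> ReLU ->
batch norm -> 2x2 max pool), the resulting feature block is reduced by
global average pooling to one vector per patch, all patch vectors are
concatenated into an embedding, and three fully connected layers with
dropout feed either a single sigmoid unit (pathway-activation score) or a
softmax layer over genes.

Keeping the extractor shallow and sharing it across all patches of a
scale keeps the whole model at a few hundred thousand parameters, which
is what makes it trainable on a few thousand images without overfitting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .exceptions import ConfigurationError
from .types import WellImage

_F32 = np.float32

SCORE_EPS = 1e-7  # sigmoid outputs are clipped to (eps, 1 - eps)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters; validated at construction."""

    scales: tuple = (1024, 512, 256)
    patch: int = 256
    filters: tuple = (4, 8, 16, 32, 64)
    kernel: int = 3
    pool: int = 2
    fc_widths: tuple = (100, 100, 100)
    dropout: float = 0.20
    head: str = "activation"  # "activation" (sigmoid) or "gene" (softmax)
    n_genes: int = 7
    share_within_scale: bool = True
    share_across_scales: bool = False

    def __post_init__(self):
        object.__setattr__(self, "scales", tuple(int(s) for s in self.scales))
        object.__setattr__(self, "filters", tuple(int(f) for f in self.filters))
        object.__setattr__(self, "fc_widths", tuple(int(w) for w in self.fc_widths))
        if not self.scales:
            raise ConfigurationError("at least one scale is required")
        if any(a <= b for a, b in zip(self.scales, self.scales[1:])):
            raise ConfigurationError(f"scales must be strictly decreasing: {self.scales}")
        if any(s % self.patch for s in self.scales):
            raise ConfigurationError(
                f"patch {self.patch} must divide every scale {self.scales}"
            )
        shrink = self.pool ** len(self.filters)
        if self.patch % shrink or self.patch // shrink < 1:
            raise ConfigurationError(
                f"patch {self.patch} must be divisible by pool^n_modules = {shrink}"
            )
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise ConfigurationError("kernel must be a positive odd integer")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.head not in ("activation", "gene"):
            raise ConfigurationError(f"unknown head {self.head!r}")
        if self.head == "gene" and self.n_genes < 2:
            raise ConfigurationError("gene head needs n_genes >= 2")

    # -- derived geometry ---------------------------------------------------
    def patches_per_scale(self) -> tuple:
        return tuple((s // self.patch) ** 2 for s in self.scales)

    @property
    def n_patches(self) -> int:
        return sum(self.patches_per_scale())

    @property
    def feature_side(self) -> int:
        return self.patch // self.pool ** len(self.filters)

    @property
    def feature_channels(self) -> int:
        return self.filters[-1]

    @property
    def embedding_dim(self) -> int:
        return self.n_patches * self.feature_channels

    @property
    def out_dim(self) -> int:
        return 1 if self.head == "activation" else self.n_genes

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)

    def spec_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# functional pieces of the computation path (channel-last at the API boundary)

def downsample(image: np.ndarray, scales) -> list:
    """Build the image pyramid: one (s, s, C) raster per scale.

    The largest scale is returned untouched when the input already has that
    side length; smaller scales use area (local-mean) interpolation, exact
    block averaging when the ratio is an integer.
    """
    img = image.data if isinstance(image, WellImage) else image
    side = img.shape[0]
    out = []
    for s in scales:
        if s == side:
            out.append(img)
        elif side % s == 0:
            f = side // s
            c = img.shape[2]
            out.append(
                img.reshape(s, f, s, f, c).mean(axis=(1, 3)).astype(img.dtype)
            )
        else:
            out.append(
                _sk_resize(
                    img, (s, s, img.shape[2]), order=1, anti_aliasing=True,
                    preserve_range=True,
                ).astype(img.dtype)
            )
    return out


def patchify(image: np.ndarray, patch: int) -> np.ndarray:
    """Tile an (S, S, C) image into (P, patch, patch, C) in row-major order."""
    side = image.shape[0]
    if side % patch:
        raise ConfigurationError(f"patch {patch} does not divide image side {side}")
    g = side // patch
    c = image.shape[2]
    return (
        image.reshape(g, patch, g, patch, c)
        .transpose(0, 2, 1, 3, 4)
        .reshape(g * g, patch, patch, c)
    )


def unpatchify(patches: np.ndarray, side: int) -> np.ndarray:
    """Inverse of :func:`patchify` (used to verify the tiling contract)."""
    p, c = patches.shape[1], patches.shape[3]
    g = side // p
    return (
        patches.reshape(g, g, p, p, c).transpose(0, 2, 1, 3, 4).reshape(side, side, c)
    )


def global_average_pool(block: np.ndarray) -> np.ndarray:
    """(h, h, c) feature block -> length-c vector of spatial means."""
    return block.mean(axis=(0, 1))


def embed(pooled_vectors) -> np.ndarray:
    """Concatenate per-patch pooled vectors (scale-major, row-major patches)."""
    return np.concatenate([np.asarray(v).ravel() for v in pooled_vectors])


def make_pyramid(spec: ModelSpec, images: np.ndarray) -> list:
    """Precompute per-scale patch tensors for a batch of images.

    Returns one ``(N, P_s, patch, patch, 3)`` array per scale; the training
    loop caches this so the pyramid is not rebuilt every epoch. The result
    is accepted directly by :meth:`MultiScaleNet.forward`.
    """
    arr = np.asarray(images, dtype=_F32)
    if arr.ndim == 3:
        arr = arr[None]
    out = []
    for s in spec.scales:
        out.append(
            np.stack(
                [patchify(downsample(img, (s,))[0], spec.patch) for img in arr]
            )
        )
    return out


def _make_extractor(spec: ModelSpec, rng: np.random.Generator) -> nn.Sequential:
    layers = []
    c_in = 3
    for mi, c_out in enumerate(spec.filters):
        layers += [
            nn.Conv2d(c_in, c_out, spec.kernel, rng, first=(mi == 0)),
            nn.ReLU(),
            nn.BatchNorm2d(c_out),
            nn.MaxPool2d(spec.pool),
        ]
        c_in = c_out
    return nn.Sequential(layers)


def _make_head(spec: ModelSpec, rng: np.random.Generator) -> nn.Sequential:
    layers = []
    d = spec.embedding_dim
    for i, width in enumerate(spec.fc_widths):
        layers += [nn.Dense(d, width, rng), nn.ReLU()]
        if i < len(spec.fc_widths) - 1:  # dropout between FC layers only
            layers.append(nn.Dropout(spec.dropout))
        d = width
    layers.append(nn.Dense(d, spec.out_dim, rng))
    return nn.Sequential(layers)


class MultiScaleNet:
    """The assembled network: pyramid -> patches -> extractor -> head."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        n_scales = len(spec.scales)
        if spec.share_across_scales:
            shared = _make_extractor(spec, rng)
            self.extractors = [[shared]] * n_scales
        elif spec.share_within_scale:
            self.extractors = [[_make_extractor(spec, rng)] for _ in range(n_scales)]
        else:
            self.extractors = [
                [_make_extractor(spec, rng) for _ in range(p)]
                for p in spec.patches_per_scale()
            ]
        self.head = _make_head(spec, rng)

    # -- parameter plumbing -------------------------------------------------
    def _unique_extractors(self):
        seen, out = set(), []
        for group in self.extractors:
            for ex in group:
                if id(ex) not in seen:
                    seen.add(id(ex))
                    out.append(ex)
        return out

    def param_items(self):
        for ex in self._unique_extractors():
            yield from ex.param_items()
        yield from self.head.param_items()

    def zero_grad(self):
        for ex in self._unique_extractors():
            ex.zero_grad()
        self.head.zero_grad()

    def adopt_bn_stats(self):
        """Freeze pooled batch-norm statistics for inference (see nn module)."""
        for ex in self._unique_extractors():
            for layer in ex.layers:
                if isinstance(layer, nn.BatchNorm2d):
                    layer.adopt_pooled_stats()

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.param_items())

    # -- forward / backward -------------------------------------------------
    def _prepare(self, images: np.ndarray) -> np.ndarray:
        """Accept (H,W,3), (N,H,W,3) or WellImage; return (N,H,W,3) float32."""
        if isinstance(images, WellImage):
            images = images.data
        arr = np.asarray(images, dtype=_F32)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4 or arr.shape[3] != 3:
            raise ConfigurationError(f"expected (N, H, W, 3) input, got {arr.shape}")
        if arr.shape[1] != self.spec.scales[0] or arr.shape[2] != self.spec.scales[0]:
            raise ConfigurationError(
                f"input side {arr.shape[1:3]} does not match largest scale "
                f"{self.spec.scales[0]}; resize at load time"
            )
        return arr

    def forward(self, images, train: bool = False, rng=None) -> np.ndarray:
        """Return raw logits, shape (N,) for the activation head, (N, G) for genes.

        ``images`` is either an (N, S, S, 3) array (the pyramid is built on
        the fly) or a precomputed pyramid from :func:`make_pyramid`.
        """
        spec = self.spec
        self._bwd_meta = []
        flats = []
        if isinstance(images, (list, tuple)):
            n = images[0].shape[0]
            for si, (s, per_scale) in enumerate(zip(spec.scales, images)):
                p_count = (s // spec.patch) ** 2
                flats.append(
                    np.ascontiguousarray(per_scale).reshape(
                        n * p_count, spec.patch, spec.patch, 3
                    )
                )
                if train:
                    self._bwd_meta.append((si, p_count))
        else:
            arr = self._prepare(images)
            n = arr.shape[0]
            for si, s in enumerate(spec.scales):
                pyr = np.stack([downsample(arr[i], (s,))[0] for i in range(n)])
                p_count = (s // spec.patch) ** 2
                patches = np.stack([patchify(pyr[i], spec.patch) for i in range(n)])
                flats.append(patches.reshape(n * p_count, spec.patch, spec.patch, 3))
                if train:
                    self._bwd_meta.append((si, p_count))
        feats = []
        if spec.share_across_scales:
            # one shared extractor: run all scales' patches as a single batch
            # (patches have a common side) so its backward caches stay valid
            block = self.extractors[0][0].forward(
                np.concatenate(flats), train=train, rng=rng
            )
            pooled_all = block.mean(axis=(1, 2))
            offset = 0
            for flat, p_count in zip(flats, spec.patches_per_scale()):
                seg = pooled_all[offset : offset + flat.shape[0]]
                offset += flat.shape[0]
                feats.append(seg.reshape(n, p_count * spec.feature_channels))
        else:
            for si, flat in enumerate(flats):
                p_count = flat.shape[0] // n
                if len(self.extractors[si]) == 1:
                    block = self.extractors[si][0].forward(flat, train=train, rng=rng)
                    pooled = block.mean(axis=(1, 2))  # (n*P, c)
                else:  # one extractor per patch position
                    per_patch = flat.reshape(n, p_count, spec.patch, spec.patch, 3)
                    pooled_parts = []
                    for pi, ex in enumerate(self.extractors[si]):
                        b = ex.forward(
                            np.ascontiguousarray(per_patch[:, pi]), train=train, rng=rng
                        )
                        pooled_parts.append(b.mean(axis=(1, 2)))
                    pooled = np.stack(pooled_parts, axis=1).reshape(n * p_count, -1)
                feats.append(pooled.reshape(n, p_count * spec.feature_channels))
        embedding = np.concatenate(feats, axis=1).astype(_F32)
        z = self.head.forward(embedding, train=train, rng=rng)
        if spec.head == "activation":
            z = z[:, 0]
        return z

    def backward(self, dz: np.ndarray) -> None:
        """Backpropagate loss gradients w.r.t. logits; accumulates into grads."""
        spec = self.spec
        if spec.head == "activation":
            dz = np.asarray(dz, _F32).reshape(-1, 1)
        demb = self.head.backward(np.asarray(dz, _F32))
        n = demb.shape[0]
        c = spec.feature_channels
        h = spec.feature_side
        offset = 0
        dblocks = []
        for si, p_count in self._bwd_meta:
            dpool = demb[:, offset : offset + p_count * c].reshape(n * p_count, c)
            offset += p_count * c
            # gradient through global average pooling
            dblocks.append(
                np.broadcast_to(
                    dpool[:, None, None, :] / (h * h), (n * p_count, h, h, c)
                ).astype(_F32)
            )
        if spec.share_across_scales:
            self.extractors[0][0].backward(np.concatenate(dblocks))
        else:
            for (si, p_count), dblock in zip(self._bwd_meta, dblocks):
                if len(self.extractors[si]) == 1:
                    self.extractors[si][0].backward(dblock)
                else:
                    db = dblock.reshape(n, p_count, h, h, c)
                    for pi, ex in enumerate(self.extractors[si]):
                        ex.backward(np.ascontiguousarray(db[:, pi]))
        self._bwd_meta = []

    # -- inference ----------------------------------------------------------
    def predict(self, images, batch: int = 8) -> np.ndarray:
        """Head outputs: activation scores in (0, 1) or per-gene probabilities."""
        arr = self._prepare(images)
        outs = []
        for i in range(0, arr.shape[0], batch):
            z = self.forward(arr[i : i + batch], train=False)
            if self.spec.head == "activation":
                outs.append(np.clip(nn.sigmoid(z), SCORE_EPS, 1 - SCORE_EPS))
            else:
                outs.append(nn.softmax(z))
        return np.concatenate(outs)

    def extract_features(self, patch: np.ndarray, scale_index: int = 0,
                         patch_index: int = 0) -> np.ndarray:
        """Run one (patch, patch, 3) raster through a feature extractor.

        Returns the (h, h, c) block preceding global average pooling.
        """
        if patch.shape[:2] != (self.spec.patch, self.spec.patch):
            raise ConfigurationError(
                f"patch side must be {self.spec.patch}, got {patch.shape[:2]}"
            )
        x = np.asarray(patch, _F32)[None]
        group = self.extractors[scale_index]
        ex = group[min(patch_index, len(group) - 1)]
        block = ex.forward(x, train=False)
        return block[0]

    # -- state --------------------------------------------------------------
    def state_arrays(self):
        """All learnable parameters plus batch-norm running statistics."""
        arrays = {}
        def add(prefix, seq):
            for li, layer in enumerate(seq.layers):
                for name, arr in layer.params().items():
                    arrays[f"{prefix}.{li}.{name}"] = arr
                if isinstance(layer, nn.BatchNorm2d):
                    arrays[f"{prefix}.{li}.running_mean"] = layer.running_mean
                    arrays[f"{prefix}.{li}.running_var"] = layer.running_var
        for ei, ex in enumerate(self._unique_extractors()):
            add(f"extractor{ei}", ex)
        add("head", self.head)
        return arrays

    def copy_state(self) -> dict:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def load_state(self, state: dict) -> None:
        own = self.state_arrays()
        if set(own) != set(state):
            raise ConfigurationError("checkpoint state does not match architecture")
        for k, arr in own.items():
            if arr.shape != state[k].shape:
                raise ConfigurationError(
                    f"shape mismatch for {k}: {arr.shape} vs {state[k].shape}"
                )
            arr[...] = state[k]


def count_parameters(spec: ModelSpec) -> int:
    """Exact number of trainable scalars for a spec (conv, BN, FC, head)."""
    return MultiScaleNet(spec, seed=0).n_parameters()


# ---------------------------------------------------------------------------
# public losses on head outputs (probabilities)

def binary_cross_entropy(scores, labels, eps: float = 1e-12) -> float:
    """Mean BCE of sigmoid scores against 0/1 labels."""
    s = np.clip(np.asarray(scores, float).ravel(), eps, 1 - eps)
    y = np.asarray(labels, float).ravel()
    return float(-np.mean(y * np.log(s) + (1 - y) * np.log(1 - s)))


def categorical_cross_entropy(probs, onehot, eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy of probability rows against one-hot rows."""
    p = np.clip(np.asarray(probs, float), eps, None)
    return float(-np.mean(np.sum(np.asarray(onehot, float) * np.log(p), axis=1)))


# ---------------------------------------------------------------------------
# checkpoint I/O (single .npz with embedded spec + hash)

def save_checkpoint(path, net: MultiScaleNet) -> None:
    meta = json.dumps({"spec": net.spec.to_dict(), "hash": net.spec.spec_hash()})
    np.savez_compressed(path, __meta__=np.array(meta), **net.state_arrays())


def load_checkpoint(path) -> MultiScaleNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        spec = ModelSpec.from_dict(meta["spec"])
        if spec.spec_hash() != meta["hash"]:
            raise ConfigurationError("checkpoint spec hash mismatch")
        state = {k: data[k] for k in data.files if k != "__meta__"}
    net = MultiScaleNet(spec, seed=0)
    net.load_state(state)
    return net


def spec_to_yaml(spec: ModelSpec, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh)


def spec_from_yaml(path) -> ModelSpec:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("scales", "filters", "fc_widths"):
        if key in d:
            d[key] = tuple(d[key])
    return ModelSpec(**d)
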