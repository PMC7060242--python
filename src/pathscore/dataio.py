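"""Well-image and manifest I/O plus plate-stratified dataset splitting.

Images are 3-page (or RGB) TIFFs in the channel order nuclear stain,
transfection marker, reporter; manifests are plain CSV. Splitting is done
at the plate level - all images from one physical plate land in the same
partition - which is what protects the evaluation from plate-level batch
effects leaking across splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError, SplitError
from .types import CHANNEL_ROLES, WellImage

MANIFEST_COLUMNS = [
    "image_path", "plate_id", "well_id", "gene", "variant",
    "annotation_class", "drug", "concentration_nM", "truth_alpha",
]

#: plate counts up to this size are split by exhaustive search, larger
#: ones by greedy largest-first assignment
_EXACT_SEARCH_MAX_PLATES = 12


def load_image(path) -> WellImage:
    """Read a 3-page or RGB TIFF into a float [0, 1] channel-last raster."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if len(pages) > 1:
        if len({p.shape for p in pages}) != 1 or pages[0].ndim != 2:
            raise FormatError(f"{path}: inconsistent TIFF page shapes")
        arr = np.stack(pages, axis=-1)  # pages -> channel-last
    else:
        arr = pages[0]
    if arr.ndim == 3 and arr.shape[0] in (2, 3, 4) and arr.shape[0] != arr.shape[2]:
        arr = np.moveaxis(arr, 0, 2)  # planar RGB -> channel-last
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"{path}: expected 3 channels, got shape {arr.shape}"
        )
    if np.issubdtype(arr.dtype, np.integer):
        scale = np.iinfo(arr.dtype).max
        data = arr.astype(np.float32) / scale
    else:
        data = arr.astype(np.float32)
    roles = _read_roles(path)
    return WellImage(data, roles)


def _read_roles(path) -> tuple:
    try:
        with tifffile.TiffFile(path) as tf:
            roles = tuple(
                (p.description or "").strip() for p in tf.pages[:3]
            )
        if all(roles) and len(set(roles)) == 3:
            return roles
    except Exception:
        pass
    return CHANNEL_ROLES


def save_image(path, image: WellImage, bit_depth: int = 16) -> None:
    """Write a WellImage as a multi-page 16-bit (or 8-bit) TIFF."""
    top = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    arr = np.round(np.clip(image.data, 0, 1) * top).astype(dtype)
    with tifffile.TiffWriter(path) as tw:
        for ch, role in enumerate(image.channel_roles):
            tw.write(arr[..., ch], description=role, contiguous=False)


def load_as_array(image: WellImage, side: int) -> np.ndarray:
    """Resize (area interpolation) to the model's largest scale if needed."""
    from .model import downsample  # local import to avoid a cycle

    if image.side == side:
        return image.data
    if image.side < side:
        from skimage.transform import resize

        return resize(
            image.data, (side, side, 3), order=1, anti_aliasing=True,
            preserve_range=True,
        ).astype(np.float32)
    return downsample(image.data, (side,))[0]


@dataclass
class Dataset:
    """A manifest-backed collection of well images."""

    manifest: pd.DataFrame
    root: Path
    channel_roles: tuple = CHANNEL_ROLES

    def __post_init__(self):
        self.root = Path(self.root)
        missing = [c for c in ("image_path", "plate_id") if c not in self.manifest.columns]
        if missing:
            raise FormatError(f"manifest lacks required columns: {missing}")
        if self.manifest["plate_id"].astype(str).str.len().eq(0).any():
            raise FormatError("manifest contains empty plate_id values")

    @classmethod
    def from_manifest(cls, manifest_path, root=None) -> "Dataset":
        manifest_path = Path(manifest_path)
        df = pd.read_csv(manifest_path)
        return cls(df, root or manifest_path.parent)

    def __len__(self) -> int:
        return len(self.manifest)

    @property
    def plate_ids(self) -> list:
        return sorted(self.manifest["plate_id"].astype(str).unique())

    def image_path(self, i: int) -> Path:
        return self.root / self.manifest.iloc[i]["image_path"]

    def load_image(self, i: int) -> WellImage:
        return load_image(self.image_path(i))

    def load_arrays(self, side: int) -> np.ndarray:
        """All images as one (N, side, side, 3) float32 array."""
        return np.stack(
            [load_as_array(self.load_image(i), side) for i in range(len(self))]
        )

    def subset(self, mask) -> "Dataset":
        return Dataset(
            self.manifest[mask].reset_index(drop=True), self.root, self.channel_roles
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions, applied at plate granularity."""

    fractions: tuple = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        f = tuple(float(x) for x in self.fractions)
        object.__setattr__(self, "fractions", f)
        if len(f) != 3 or any(x <= 0 for x in f):
            raise SplitError("need three positive fractions")
        if abs(sum(f) - 1.0) > 1e-9:
            raise SplitError(f"fractions must sum to 1, got {sum(f)}")


def _assignment_deviation(sizes, assign, targets, total):
    dev = 0.0
    for s in range(3):
        achieved = sum(sz for sz, a in zip(sizes, assign) if a == s) / total
        dev += abs(achieved - targets[s])
    return dev


def _exact_split(sizes, targets):
    """Minimize sum |achieved - target| over all 3-way plate partitions."""
    n = len(sizes)
    total = sum(sizes)
    codes = np.arange(3**n)
    digits = (codes[:, None] // 3 ** np.arange(n)[None, :]) % 3  # (3^n, n)
    sizes_arr = np.asarray(sizes, dtype=float)
    dev = np.zeros(len(codes))
    nonempty = np.ones(len(codes), dtype=bool)
    for s in range(3):
        member = digits == s
        achieved = member @ sizes_arr / total
        dev += np.abs(achieved - targets[s])
        nonempty &= member.any(axis=1)  # every split gets at least one plate
    dev[~nonempty] = np.inf
    return list(digits[int(np.argmin(dev))])


def _greedy_split(sizes, targets):
    """Largest plate first, each to the split with the largest deficit."""
    total = sum(sizes)
    order = sorted(range(len(sizes)), key=lambda i: -sizes[i])
    counts = [0.0, 0.0, 0.0]
    assign = [0] * len(sizes)
    for i in order:
        deficits = [targets[s] * total - counts[s] for s in range(3)]
        s = int(np.argmax(deficits))
        assign[i] = s
        counts[s] += sizes[i]
    # guarantee non-empty splits
    for s in range(3):
        if s not in assign:
            donor = max(range(3), key=lambda t: assign.count(t))
            movable = min(
                (i for i in range(len(sizes)) if assign[i] == donor),
                key=lambda i: sizes[i],
            )
            assign[movable] = s
    return assign


def split_by_plate(dataset: Dataset, spec: SplitSpec):
    """Partition a dataset into (train, val, test) with plates kept atomic.

    Plate-to-split assignment minimizes the total absolute deviation of the
    achieved image fractions from the requested ones: exhaustively for small
    plate counts, greedily (largest plate first) beyond that. The seed
    permutes plate order first, so ties are broken reproducibly at random.
    """
    plates = dataset.manifest["plate_id"].astype(str)
    plate_ids = sorted(plates.unique())
    if len(plate_ids) < 3:
        raise SplitError(f"need at least 3 plates to split, got {len(plate_ids)}")
    rng = np.random.default_rng(spec.seed)
    plate_ids = [plate_ids[i] for i in rng.permutation(len(plate_ids))]
    sizes = [int((plates == p).sum()) for p in plate_ids]

    if len(plate_ids) <= _EXACT_SEARCH_MAX_PLATES:
        assign = _exact_split(sizes, spec.fractions)
    else:
        assign = _greedy_split(sizes, spec.fractions)

    split_of = {p: s for p, s in zip(plate_ids, assign)}
    labels = plates.map(lambda p: ("train", "val", "test")[split_of[p]])
    parts = tuple(dataset.subset((labels == name).values) for name in ("train", "val", "test"))
    return parts


def write_split(dataset: Dataset, parts, path) -> pd.DataFrame:
    """Write the manifest with an added ``split`` column."""
    frames = []
    for name, part in zip(("train", "val", "test"), parts):
        df = part.manifest.copy()
        df["split"] = name
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)
    return out
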