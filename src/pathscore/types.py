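"""Shared value types: images and well metadata records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical channel order used throughout the package
CHANNEL_ROLES = ("nuclear", "marker", "reporter")

#: annotation classes a variant may carry in a manifest
ANNOTATION_CLASSES = ("WT", "activating", "predicted", "VUS")


@dataclass
class WellImage:
    """One field of view: an (H, W, 3) float raster in [0, 1], channel-last.

    Channels are, in order: nuclear stain (DAPI), transfection marker
    (mCherry) and pathway reporter (GFP-tagged ERK2/STAT3).
    """

    data: np.ndarray
    channel_roles: tuple = CHANNEL_ROLES

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[2] != len(self.channel_roles):
            raise ValueError(
                f"WellImage expects (H, W, {len(self.channel_roles)}) data, "
                f"got {self.data.shape}"
            )

    @property
    def side(self) -> int:
        return self.data.shape[0]

    def channel(self, role: str) -> np.ndarray:
        return self.data[..., self.channel_roles.index(role)]


@dataclass
class WellRecord:
    """Manifest row describing one well image."""

    image_path: str
    plate_id: str
    well_id: str
    gene: str
    variant: str
    annotation_class: str
    drug: str | None = None
    concentration_nM: float | None = None
    truth_alpha: float | None = field(default=None)  # synthetic ground truth only
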