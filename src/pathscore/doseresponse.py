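"""Dose-response series from drug-treated wells.

The series stays non-parametric on purpose: each point is the mean
network score of all images at one concentration with its standard error
of the mean, which is exactly what the assay reports. Potency comparison
and rebound detection are descriptive operations on those points, not
curve fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError


@dataclass
class DoseResponseSeries:
    """Per-(variant, drug) curve: mean score and SEM at each concentration."""

    gene: str
    variant: str
    drug: str
    points: pd.DataFrame  # columns: concentration_nM, mean, sem, n_images

    def __post_init__(self):
        pts = self.points
        if (pts["n_images"] < 1).any():
            raise DataError("every dose point needs at least one image")
        self.points = pts.sort_values("concentration_nM").reset_index(drop=True)

    @property
    def concentrations(self) -> np.ndarray:
        return self.points["concentration_nM"].to_numpy(float)

    @property
    def means(self) -> np.ndarray:
        return self.points["mean"].to_numpy(float)

    @property
    def sems(self) -> np.ndarray:
        return self.points["sem"].to_numpy(float)

    def to_frame(self) -> pd.DataFrame:
        df = self.points.copy()
        df.insert(0, "drug", self.drug)
        df.insert(0, "variant", self.variant)
        df.insert(0, "gene", self.gene)
        return df


def build_series(scored: pd.DataFrame) -> list:
    """Group scored images by (gene, variant, drug, concentration).

    ``scored`` is a manifest with a ``score`` column (see
    :func:`pathscore.scoring.score_dataset`); rows without a drug are
    treated as the zero-dose condition of any drug present for that
    variant, so untreated baseline wells join every series.
    """
    df = scored.copy()
    if "score" not in df.columns:
        raise DataError("scored frame lacks a 'score' column")
    treated = df[df["drug"].notna()]
    out = []
    for (gene, variant, drug), grp in treated.groupby(
        ["gene", "variant", "drug"], sort=True
    ):
        grp = grp.copy()
        baseline = df[
            (df["gene"] == gene) & (df["variant"] == variant) & df["drug"].isna()
        ]
        if not baseline.empty:
            baseline = baseline.assign(drug=drug, concentration_nM=0.0)
            grp = pd.concat([baseline, grp], ignore_index=True)
        rows = []
        for conc, cgrp in grp.groupby("concentration_nM", sort=True):
            s = cgrp["score"].to_numpy(float)
            sem = float(s.std(ddof=1) / np.sqrt(s.size)) if s.size > 1 else 0.0
            rows.append(
                {"concentration_nM": float(conc), "mean": float(s.mean()),
                 "sem": sem, "n_images": int(s.size)}
            )
        out.append(DoseResponseSeries(gene, variant, drug, pd.DataFrame(rows)))
    return out


def series_frame(series_list) -> pd.DataFrame:
    """Tidy export of many series (one row per dose point)."""
    return pd.concat([s.to_frame() for s in series_list], ignore_index=True)


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PotencyReport:
    """Lowest concentration at which each series drops below its threshold."""

    threshold_a: float
    threshold_b: float
    first_drop_a: float | None
    first_drop_b: float | None
    more_potent: str | None  # label of the faster-dropping series, None on tie
    tie: bool


def _first_drop(series: DoseResponseSeries, threshold: float):
    below = series.means < threshold
    idx = np.flatnonzero(below)
    return float(series.concentrations[idx[0]]) if idx.size else None


def compare_potency(series_a: DoseResponseSeries, series_b: DoseResponseSeries,
                    threshold: float | None = None) -> PotencyReport:
    """Which series reaches its drop threshold at the lower concentration.

    The default threshold is per-series: halfway between the zero-dose (or
    lowest-dose) mean and the series minimum. Purely descriptive; requires
    overlapping concentration support.
    """
    overlap = set(series_a.concentrations) & set(series_b.concentrations)
    if not overlap:
        raise DataError("series have no overlapping concentrations")

    def default_thr(s):
        return 0.5 * (s.means[0] + s.means.min())

    thr_a = default_thr(series_a) if threshold is None else threshold
    thr_b = default_thr(series_b) if threshold is None else threshold
    drop_a = _first_drop(series_a, thr_a)
    drop_b = _first_drop(series_b, thr_b)
    if drop_a is None and drop_b is None:
        winner, tie = None, True
    elif drop_b is None or (drop_a is not None and drop_a < drop_b):
        winner, tie = f"{series_a.variant}:{series_a.drug}", False
    elif drop_a is None or drop_b < drop_a:
        winner, tie = f"{series_b.variant}:{series_b.drug}", False
    else:
        winner, tie = None, True
    return PotencyReport(thr_a, thr_b, drop_a, drop_b, winner, tie)


@dataclass(frozen=True)
class ReboundReport:
    detected: bool
    min_concentration: float | None  # concentration of the pre-rise minimum
    rise: float                      # largest qualifying rise found


def detect_rebound(series: DoseResponseSeries) -> ReboundReport:
    """Flag a high-dose re-activation bump in a dose-response series.

    Scans for a running minimum followed at a higher concentration by a
    mean that rises above it by more than twice the standard error of the
    difference of the two points; fluctuations inside that band are not
    flagged. Needs at least 4 concentrations.
    """
    if len(series.points) < 4:
        raise DataError("rebound detection needs >= 4 concentrations")
    means, sems, concs = series.means, series.sems, series.concentrations
    best_rise, best_conc, detected = 0.0, None, False
    min_i = 0
    for j in range(1, len(means)):
        if means[j] < means[min_i]:
            min_i = j
            continue
        rise = means[j] - means[min_i]
        band = 2.0 * float(np.hypot(sems[j], sems[min_i]))
        if rise > band and rise > best_rise:
            detected = True
            best_rise = rise
            best_conc = float(concs[min_i])
    return ReboundReport(detected, best_conc, float(best_rise))
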