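"""Per-image activation scores and variant-level aggregation.

A variant's activity call averages the network's sigmoid output over all
of its images and compares the mean to the sigmoid midpoint: strictly
above 0.5 is called active, 0.5 or below inactive. Sub-threshold variants
can still differ significantly from wildtype, which the two-sample t-test
against wildtype scores captures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import Dataset
from .exceptions import DataError
from .model import MultiScaleNet


def score_images(net: MultiScaleNet, images, batch: int = 8) -> np.ndarray:
    """One activation score in (0, 1) per image; deterministic."""
    if isinstance(images, Dataset):
        images = images.load_arrays(net.spec.scales[0])
    return net.predict(images, batch=batch)


def score_dataset(net: MultiScaleNet, dataset: Dataset, batch: int = 8) -> pd.DataFrame:
    """Manifest plus a ``score`` column."""
    df = dataset.manifest.copy()
    df["score"] = score_images(net, dataset, batch=batch)
    return df


@dataclass(frozen=True)
class VariantSummary:
    gene: str
    variant: str
    annotation_class: str
    n_images: int
    mean_score: float
    sem: float

    @property
    def call(self) -> str:
        # strictly above the sigmoid midpoint counts as active
        return "active" if self.mean_score > 0.5 else "inactive"


def summarize_variant(scores, gene: str, variant: str,
                      annotation_class: str) -> VariantSummary:
    """Mean, SEM and activity call for one variant's per-image scores."""
    s = np.asarray(scores, float).ravel()
    if s.size == 0:
        raise DataError(f"no scores for variant {variant}")
    sem = float(s.std(ddof=1) / np.sqrt(s.size)) if s.size > 1 else 0.0
    return VariantSummary(gene, variant, annotation_class, int(s.size),
                          float(s.mean()), sem)


def summarize_all(scored: pd.DataFrame) -> list:
    """One :class:`VariantSummary` per (gene, variant) group."""
    out = []
    for (gene, variant), grp in scored.groupby(["gene", "variant"], sort=True):
        out.append(
            summarize_variant(
                grp["score"].to_numpy(), gene, variant,
                str(grp["annotation_class"].iloc[0]),
            )
        )
    return out


def summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene, "variant": s.variant,
                "annotation_class": s.annotation_class, "n_images": s.n_images,
                "mean_score": s.mean_score, "sem": s.sem, "call": s.call,
            }
            for s in summaries
        ]
    )


def class_breakdown(summaries) -> pd.DataFrame:
    """Active-call counts per (annotation class, gene) with a total per class.

    Wildtype rows are not tabulated (the breakdown describes mutations) and
    classes absent from the dataset are simply omitted.
    """
    rows = []
    df = summaries_frame(summaries)
    df = df[df["annotation_class"] != "WT"]
    for cls, cgrp in df.groupby("annotation_class", sort=True):
        for gene, ggrp in cgrp.groupby("gene", sort=True):
            n_active = int((ggrp["call"] == "active").sum())
            n_total = int(len(ggrp))
            rows.append(
                {"annotation_class": cls, "gene": gene, "n_active": n_active,
                 "n_total": n_total, "percent_active": 100.0 * n_active / n_total}
            )
        n_active = int((cgrp["call"] == "active").sum())
        n_total = int(len(cgrp))
        rows.append(
            {"annotation_class": cls, "gene": "Total", "n_active": n_active,
             "n_total": n_total, "percent_active": 100.0 * n_active / n_total}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variant-name parsing (HGVS-like protein notation, tolerant of ad-hoc forms)

_POS_RE = re.compile(r"(?:^|[^A-Za-z0-9])?([A-Z](?:[a-z]{2})?)(\d+)")


def parse_variant_position(name: str):
    """Anchor residue position of a protein variant name.

    Handles substitutions (``V654A``, ``p.Val654Ala``), deletions and
    ad-hoc compound forms (``W557_558Del``, ``G12_G13_Del_Ins_DC``); the
    anchor is the first residue position mentioned. Raises ValueError for
    names with no residue position (e.g. ``WT``).
    """
    s = str(name).strip()
    if s.startswith("p."):
        s = s[2:]
    m = _POS_RE.search(s)
    if not m:
        raise ValueError(f"no residue position in variant name {name!r}")
    return int(m.group(2))


def position_profile(summaries):
    """Long-format per-residue table for lollipop-style summaries.

    Returns ``(profile, rejects)``: profile rows carry the anchor position,
    the variant's mean score and class; unparseable names land in the
    rejects table with the reason instead of being dropped silently.
    """
    rows, rejects = [], []
    for s in summaries:
        if s.annotation_class == "WT":
            continue
        try:
            pos = parse_variant_position(s.variant)
        except ValueError as exc:
            rejects.append({"variant": s.variant, "reason": str(exc)})
            continue
        rows.append(
            {"gene": s.gene, "variant": s.variant, "position": pos,
             "mean_score": s.mean_score, "annotation_class": s.annotation_class,
             "call": s.call}
        )
    profile = pd.DataFrame(rows)
    if not profile.empty:
        profile = profile.sort_values(["gene", "position"]).reset_index(drop=True)
    return profile, pd.DataFrame(rejects)


# ---------------------------------------------------------------------------
# variant vs wildtype comparison

@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float


def compare_to_wt(variant_scores, wt_scores, equal_var: bool = False) -> TTestResult:
    """Two-sample t-test of per-image scores against wildtype.

    Welch's unequal-variance form by default; ``equal_var=True`` restores
    the pooled-variance test. Groups need at least two observations each,
    and two constant groups are rejected as degenerate rather than
    returning NaN.
    """
    a = np.asarray(variant_scores, float).ravel()
    b = np.asarray(wt_scores, float).ravel()
    if a.size < 2 or b.size < 2:
        raise DataError("need at least 2 scores per group for a t-test")
    if np.ptp(a) < 1e-12 and np.ptp(b) < 1e-12:
        raise DataError("both groups are constant; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))
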