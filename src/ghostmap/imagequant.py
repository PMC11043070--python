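"""Cell segmentation, intensity quantification, ghost classification and
cohort statistics.

The workflow mirrors a standard reporter-based quantification: reporter-
positive cells are segmented as thresholded connected components (8-connected
on 2D maximum projections, 26-connected in 3D), per-cell mean and maximum
intensities are measured for every channel, cells are split into typical
(marker-positive) and ghost (marker-negative) by their mean identity-marker
intensity, and marker co-positivity is called per channel.  Statistics are
aggregated per animal (sections pooled first) to avoid pseudo-replication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .core import (
    CellTable, InsufficientDataError, SchemaError, ValidationError,
)


@dataclass
class SegmentationParams:
    threshold_method: str = "otsu"       # otsu | fixed
    fixed_threshold: float = 0.0
    min_size: float = 10.0               # um^2 (2D) or um^3 (3D)
    max_size: float = 1.0e5
    projection: str = "max"              # max | none

    def __post_init__(self) -> None:
        if self.min_size >= self.max_size:
            raise ValidationError("min_size must be < max_size")
        if self.fixed_threshold < 0:
            raise ValidationError("fixed_threshold must be >= 0")


@dataclass
class ClassificationParams:
    """How mean identity-marker intensity is thresholded into typical/ghost."""
    pomc_channel: str = "pomc"
    statistic: str = "mean"
    threshold_rule: str = "otsu_on_cells"  # fixed | quantile_of_negative_control | otsu_on_cells
    fixed_threshold: float = 0.0
    quantile: float = 0.95
    marker_rules: dict[str, dict] = field(default_factory=dict)
    # marker_rules: marker -> {"statistic": "max"|"mean", "threshold": float}


def _resolve_threshold(image: np.ndarray, params: SegmentationParams) -> float:
    if params.threshold_method == "fixed":
        return params.fixed_threshold
    vals = image.ravel()
    if np.ptp(vals) == 0:
        warnings.warn("degenerate (constant) image; threshold set above maximum",
                      stacklevel=3)
        return float(vals[0]) + 1.0
    return float(threshold_otsu(vals))


def _segment(image: np.ndarray, unit_size: float, params: SegmentationParams,
             connectivity: int) -> np.ndarray:
    thr = _resolve_threshold(image, params)
    mask = image >= thr
    labels = cc_label(mask, connectivity=connectivity)
    if labels.max() == 0:
        return labels
    sizes = np.bincount(labels.ravel())[1:] * unit_size
    keep = np.flatnonzero((sizes >= params.min_size) & (sizes <= params.max_size)) + 1
    relabel = np.zeros(labels.max() + 1, dtype=labels.dtype)
    relabel[keep] = np.arange(1, len(keep) + 1)
    return relabel[labels]


def segment_cells_2d(stack: dict[str, np.ndarray], reporter_channel: str,
                     params: SegmentationParams | None = None,
                     voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     ) -> tuple[np.ndarray, CellTable]:
    """Segment reporter-positive cells on the reporter max projection.

    Returns the 2D label map and a skeleton cell table with centroids (um;
    projected z = stack mid-plane) and projected areas (um^2).
    """
    params = params or SegmentationParams()
    if reporter_channel not in stack:
        raise SchemaError(f"reporter channel {reporter_channel!r} not in stack; "
                          f"available: {sorted(stack)}")
    vol = stack[reporter_channel]
    if vol.size == 0:
        raise ValidationError("empty stack")
    vz, vy, vx = voxel_size
    image = vol.max(axis=0) if (params.projection == "max" and vol.ndim == 3) else vol
    labels = _segment(image, vy * vx, params, connectivity=2)
    mid_z = vol.shape[0] / 2.0 * vz if vol.ndim == 3 else 0.0
    rows = []
    for i in range(1, labels.max() + 1):
        ys, xs = np.nonzero(labels == i)
        rows.append({
            "cell_id": f"roi{i:04d}", "animal_id": "a0",
            "x": (xs.mean() + 0.5) * vx, "y": (ys.mean() + 0.5) * vy, "z": mid_z,
            "area_or_volume": len(xs) * vy * vx,
        })
    cols = ["cell_id", "animal_id", "x", "y", "z", "area_or_volume"]
    return labels, CellTable(pd.DataFrame(rows, columns=cols))


def segment_cells_3d(stack: dict[str, np.ndarray], reporter_channel: str,
                     params: SegmentationParams | None = None,
                     voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     ) -> tuple[np.ndarray, CellTable]:
    """As :func:`segment_cells_2d` but 26-connected components in 3D with a
    volume filter (um^3) and true 3D centroids."""
    params = params or SegmentationParams()
    if reporter_channel not in stack:
        raise SchemaError(f"reporter channel {reporter_channel!r} not in stack; "
                          f"available: {sorted(stack)}")
    vol = stack[reporter_channel]
    if vol.size == 0:
        raise ValidationError("empty stack")
    vz, vy, vx = voxel_size
    labels = _segment(vol, vz * vy * vx, params, connectivity=3)
    rows = []
    for i in range(1, labels.max() + 1):
        zs, ys, xs = np.nonzero(labels == i)
        rows.append({
            "cell_id": f"roi{i:04d}", "animal_id": "a0",
            "x": (xs.mean() + 0.5) * vx, "y": (ys.mean() + 0.5) * vy,
            "z": (zs.mean() + 0.5) * vz,
            "area_or_volume": len(xs) * vz * vy * vx,
        })
    cols = ["cell_id", "animal_id", "x", "y", "z", "area_or_volume"]
    return labels, CellTable(pd.DataFrame(rows, columns=cols))


def quantify_rois(stack: dict[str, np.ndarray], rois: np.ndarray,
                  skeleton: CellTable | None = None) -> CellTable:
    """Per-cell mean and maximum intensity of every channel over its ROI.

    ``rois`` is a label map (2D label maps are applied to each channel's
    maximum projection).  When a segmentation skeleton is given, channel
    statistics are appended to it; otherwise a minimal table is built.
    """
    if rois.max() == 0:
        raise ValidationError("ROI labelling is empty")
    ids = np.arange(1, rois.max() + 1)
    stats = {}
    for name, vol in stack.items():
        img = vol
        if rois.ndim == 2 and vol.ndim == 3:
            img = vol.max(axis=0)
        if img.shape != rois.shape:
            raise ValidationError(
                f"ROI map shape {rois.shape} does not match channel {name!r} "
                f"shape {img.shape}")
        stats[f"{name}_mean"] = scipy.ndimage.mean(img, labels=rois, index=ids)
        stats[f"{name}_max"] = scipy.ndimage.maximum(img, labels=rois, index=ids)
    if skeleton is not None:
        if len(skeleton) != len(ids):
            raise ValidationError("skeleton row count does not match ROI count")
        df = skeleton.df.copy()
    else:
        df = pd.DataFrame({"cell_id": [f"roi{i:04d}" for i in ids],
                           "animal_id": "a0"})
    for col, vals in stats.items():
        df[col] = vals
    return CellTable(df)


# ---------------------------------------------------------------------------
# Classification and marker calls
# ---------------------------------------------------------------------------

def classify_lineage_cells(cells: CellTable,
                           params: ClassificationParams | None = None,
                           negative_control: np.ndarray | None = None,
                           ) -> tuple[CellTable, float]:
    """Split lineage-positive cells into typical vs ghost by mean marker
    intensity; returns the table and the resolved threshold.

    Cells at or above the threshold are typical; below it, ghost (the >=
    convention holds for every thresholding in the package).  A degenerate
    (constant-intensity) Otsu input classifies all cells typical with a
    warning rather than raising.
    """
    params = params or ClassificationParams()
    values = cells.channel_stat(params.pomc_channel, params.statistic)
    if params.threshold_rule == "fixed":
        thr = params.fixed_threshold
    elif params.threshold_rule == "quantile_of_negative_control":
        if negative_control is None or len(negative_control) == 0:
            raise ValidationError(
                "threshold_rule 'quantile_of_negative_control' requires "
                "negative-control intensities")
        thr = float(np.quantile(np.asarray(negative_control, float),
                                params.quantile))
    elif params.threshold_rule == "otsu_on_cells":
        if np.ptp(values) == 0:
            warnings.warn("degenerate marker distribution (all intensities "
                          "identical); all cells classified typical", stacklevel=2)
            thr = float(values[0])   # every value >= thr -> typical
        else:
            thr = float(threshold_otsu(values))
    else:
        raise ValidationError(f"unknown threshold_rule {params.threshold_rule!r}")
    df = cells.df.copy()
    lineage = df["lineage_positive"].astype(bool)
    df["class_label"] = np.where(
        ~lineage, "unassigned", np.where(values >= thr, "typical", "ghost"))
    return CellTable(df), thr


def call_marker_positivity(cells: CellTable, marker: str,
                           statistic: str = "max",
                           threshold: float = 0.0) -> CellTable:
    """Boolean per-cell call ``<marker>_pos``: statistic >= threshold."""
    values = cells.channel_stat(marker, statistic)
    df = cells.df.copy()
    df[f"{marker}_pos"] = values >= threshold
    return CellTable(df)


# ---------------------------------------------------------------------------
# Cohort summaries and statistics
# ---------------------------------------------------------------------------

def summarize_cohort(cells: CellTable, by: tuple[str, ...] = ("group",)
                     ) -> dict[str, pd.DataFrame]:
    """Per-animal class shares (sections pooled within animal first), then
    group means +- s.e.m.

    Class shares use the lineage-positive count as denominator; marker
    shares (for every ``<marker>_pos`` column) use the class size.  Animals
    with zero lineage-positive cells are excluded with a warning.
    """
    df = cells.df
    if not df["class_label"].isin(("typical", "ghost")).any():
        raise ValidationError("class_label not assigned; run classification first")
    markers = cells.markers
    rows = []
    group_keys = [k for k in by if k in df.columns]
    for animal, adf in df.groupby("animal_id"):
        adf = adf[adf["lineage_positive"].astype(bool)]
        n = len(adf)
        if n == 0:
            warnings.warn(f"animal {animal!r} has no lineage-positive cells; "
                          "excluded", stacklevel=2)
            continue
        n_typ = int((adf["class_label"] == "typical").sum())
        n_gho = int((adf["class_label"] == "ghost").sum())
        row = {"animal_id": animal, "n_cells": n,
               "n_typical": n_typ, "n_ghost": n_gho,
               "pct_typical": 100.0 * n_typ / n, "pct_ghost": 100.0 * n_gho / n}
        for key in group_keys:
            row[key] = adf[key].iloc[0]
        for m in markers:
            for cls, n_cls in (("typical", n_typ), ("ghost", n_gho)):
                sel = adf[adf["class_label"] == cls]
                row[f"pct_{m}_pos_{cls}"] = (
                    100.0 * sel[f"{m}_pos"].sum() / n_cls if n_cls else np.nan)
        rows.append(row)
    per_animal = pd.DataFrame(rows)
    value_cols = [c for c in per_animal.columns if c.startswith(("pct_", "n_"))]
    if group_keys:
        agg = per_animal.groupby(group_keys[0])[value_cols].agg(["mean", "sem"])
    else:
        agg = per_animal[value_cols].agg(["mean", "sem"]).T
    return {"per_animal": per_animal, "group_summary": agg}


def compare_groups(per_animal: pd.DataFrame, value: str, group: str = "group",
                   design: str | None = None) -> dict:
    """Two-group two-tailed t-test, or Shapiro-gated one-way ANOVA with a
    Tukey pairwise table for >= 3 groups."""
    groups = {g: sub[value].to_numpy(float)
              for g, sub in per_animal.groupby(group)}
    if any(len(v) < 2 for v in groups.values()):
        raise InsufficientDataError("every group needs >= 2 animals")
    names = sorted(groups)
    if design is None:
        design = "two_group" if len(names) == 2 else "multi_group"
    if design == "two_group":
        if len(names) != 2:
            raise ValidationError("two_group design requires exactly 2 groups")
        a, b = groups[names[0]], groups[names[1]]
        res = scipy.stats.ttest_ind(a, b)
        return {"design": "two_group", "groups": names, "t": float(res.statistic),
                "df": float(len(a) + len(b) - 2), "p": float(res.pvalue)}
    shapiro = {g: float(scipy.stats.shapiro(v).pvalue) if len(v) >= 3 else np.nan
               for g, v in groups.items()}
    normal_ok = all(np.isnan(p) or p > 0.05 for p in shapiro.values())
    f, p = scipy.stats.f_oneway(*[groups[g] for g in names])
    tk = scipy.stats.tukey_hsd(*[groups[g] for g in names])
    pairs = [{"a": names[i], "b": names[j],
              "diff": float(np.mean(groups[names[i]]) - np.mean(groups[names[j]])),
              "p": float(tk.pvalue[i, j])}
             for i in range(len(names)) for j in range(i + 1, len(names))]
    return {"design": "multi_group", "groups": names, "F": float(f),
            "p": float(p), "shapiro_p": shapiro, "normality_gate_passed": normal_ok,
            "tukey": pairs}


def correlate_with_covariate(per_animal: pd.DataFrame, value: str,
                             covariate: str) -> dict:
    """Pearson correlation of a per-animal summary with a covariate."""
    sub = per_animal[[value, covariate]].dropna()
    n_dropped = len(per_animal) - len(sub)
    if len(sub) < 3:
        raise InsufficientDataError("need >= 3 paired observations")
    x = sub[covariate].to_numpy(float)
    y = sub[value].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance; correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(sub)),
            "n_dropped": int(n_dropped)}
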