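"""TEM-style 2D mitochondrial morphometry and the three-class scheme.

Profiles from thin sections are measured for area and width-to-height
ratio, where H is the minimum Feret (caliper) width of the profile and W
the extent perpendicular to it — the minimal-width enclosing rectangle
(rotation-robust; an axis-aligned bounding-box mode is available).
The population is then split against reference thresholds — the mean area
A* and mean ratio R* of a young reference sample, shipped defaults
A* = 0.11 μm², R* = 2.34:

* elongated:  area > A* and ratio > R*
* medium:     area > A* and ratio ≤ R*
* fragmented: area ≤ A*  (ratio ignored — a pure area criterion)

Boundary equalities fall to the "smaller" class, making the classification
a deterministic partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .dynamics import StatResult, chi_squared

logger = logging.getLogger(__name__)

MORPH_CLASSES = ("elongated", "medium", "fragmented")


@dataclass(frozen=True)
class MorphologyThresholds:
    """Reference mean area (μm²) and mean W/H ratio anchoring the classes."""

    area_um2: float = 0.11
    ratio: float = 2.34

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("reference area must be positive")
        if self.ratio < 1:
            raise ValueError("reference ratio must be >= 1")


#: Thresholds derived from the young-GSC reference sample.
YOUNG_GSC_THRESHOLDS = MorphologyThresholds(0.11, 2.34)


def _corner_points(mask: np.ndarray, pixel_size: tuple[float, float]) -> np.ndarray:
    """Corner coordinates (μm) of every foreground pixel square."""
    rows, cols = np.nonzero(mask)
    py, px = pixel_size
    corners = np.concatenate([
        np.stack([rows * py, cols * px], axis=1),
        np.stack([(rows + 1) * py, cols * px], axis=1),
        np.stack([rows * py, (cols + 1) * px], axis=1),
        np.stack([(rows + 1) * py, (cols + 1) * px], axis=1),
    ])
    return np.unique(corners, axis=0)


def _hull_vertices(mask: np.ndarray, pixel_size: tuple[float, float]) -> np.ndarray:
    pts = _corner_points(np.asarray(mask, dtype=bool), pixel_size)
    if len(pts) == 0:
        raise ValueError("mask is empty")
    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices]
    except Exception:  # degenerate (collinear) masks
        return pts


def feret_extents(mask: np.ndarray, pixel_size) -> tuple[float, float]:
    """(W, H) of the minimum-width enclosing rectangle of a 2D mask, in μm.

    H is the minimum Feret (caliper) width over the convex hull's edge
    directions; W is the extent perpendicular to that minimizing direction
    — i.e. the length of the minimal-width bounding rectangle.  This is
    rotation-robust and gives an axis-aligned w×h rectangle exactly
    (w, h), unlike the max Feret diameter, which would report the
    diagonal.
    """
    py, px = _pixel_pair(pixel_size)
    verts = _hull_vertices(mask, (py, px))
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.linalg.norm(edges, axis=1)
    best = None
    for e, ln in zip(edges, lengths):
        if ln == 0:
            continue
        direction = e / ln
        normal = np.array([-direction[1], direction[0]])
        width = (verts @ normal).max() - (verts @ normal).min()
        length = (verts @ direction).max() - (verts @ direction).min()
        if best is None or width < best[1]:
            best = (max(length, width), min(width, length))
    if best is None:  # a single point
        return (min(py, px), min(py, px))
    return float(best[0]), float(best[1])


def feret_diameters(mask: np.ndarray, pixel_size) -> tuple[float, float]:
    """(max, min) Feret diameters of a binary 2D mask, in μm.

    The maximum Feret diameter is the largest pairwise hull-vertex
    distance; the minimum is the smallest caliper width over hull-edge
    directions.
    """
    py, px = _pixel_pair(pixel_size)
    verts = _hull_vertices(mask, (py, px))
    diffs = verts[:, None, :] - verts[None, :, :]
    feret_max = float(np.sqrt((diffs**2).sum(-1)).max())
    _, feret_min = feret_extents(mask, pixel_size)
    return feret_max, feret_min


def _bbox_extents(mask: np.ndarray, pixel_size) -> tuple[float, float]:
    py, px = _pixel_pair(pixel_size)
    rows, cols = np.nonzero(mask)
    h = (rows.max() - rows.min() + 1) * py
    w = (cols.max() - cols.min() + 1) * px
    return (max(w, h), min(w, h))


def _pixel_pair(pixel_size) -> tuple[float, float]:
    if np.isscalar(pixel_size):
        pair = (float(pixel_size), float(pixel_size))
    else:
        pair = (float(pixel_size[0]), float(pixel_size[1]))
    if pair[0] <= 0 or pair[1] <= 0:
        raise ValueError("pixel size must be positive")
    return pair


def measure_profile(mask: np.ndarray, pixel_size, method: str = "feret") -> dict:
    """Measure one 2D profile: area, W (max extent), H (min extent), W/H.

    ``pixel_size`` is μm per pixel (scalar or (row, col)); ``method`` is
    "feret" (default) or "bbox" for axis-aligned extents.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    if not mask.any():
        raise ValueError("mask is empty")
    py, px = _pixel_pair(pixel_size)
    area = float(mask.sum()) * py * px
    if method == "feret":
        w, h = feret_extents(mask, (py, px))
    elif method == "bbox":
        w, h = _bbox_extents(mask, (py, px))
    else:
        raise ValueError(f"unknown measurement method {method!r}")
    if h <= 0:
        h = min(py, px)
    return {"area_um2": area, "width_um": w, "height_um": h, "ratio": w / h}


def reference_thresholds(records: pd.DataFrame) -> MorphologyThresholds:
    """Freeze thresholds from a reference population: its mean area and mean ratio."""
    if len(records) == 0:
        raise ValueError("reference population is empty")
    return MorphologyThresholds(
        float(records["area_um2"].mean()), float(records["ratio"].mean())
    )


def classify_morphology(
    records: pd.DataFrame,
    thresholds: MorphologyThresholds = YOUNG_GSC_THRESHOLDS,
) -> pd.DataFrame:
    """Assign each record exactly one of elongated / medium / fragmented."""
    area = records["area_um2"].to_numpy(dtype=float)
    ratio = records["ratio"].to_numpy(dtype=float)
    cls = np.where(
        area <= thresholds.area_um2,
        "fragmented",
        np.where(ratio > thresholds.ratio, "elongated", "medium"),
    )
    out = records.copy()
    out["morph_class"] = cls
    return out


def class_counts(classified: pd.DataFrame) -> pd.Series:
    counts = classified["morph_class"].value_counts()
    return counts.reindex(MORPH_CLASSES, fill_value=0).astype(int)


def compare_populations(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    thresholds: MorphologyThresholds = YOUNG_GSC_THRESHOLDS,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[pd.DataFrame, pd.DataFrame, StatResult]:
    """Class-count table, percentages, and chi-squared homogeneity test.

    Thresholds must be fixed (e.g. frozen from the reference sample) before
    the comparison; classes empty in both populations are dropped from the
    test table, as chi-squared requires positive margins.
    """
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("both populations must be non-empty")
    counts = pd.DataFrame({
        labels[0]: class_counts(classify_morphology(records_a, thresholds)),
        labels[1]: class_counts(classify_morphology(records_b, thresholds)),
    }).T
    percentages = counts.div(counts.sum(axis=1), axis=0) * 100.0
    test_table = counts.loc[:, counts.sum(axis=0) > 0]
    if test_table.shape[1] < counts.shape[1]:
        dropped = [c for c in counts.columns if c not in test_table.columns]
        logger.info("classes empty in both populations dropped from test: %s", dropped)
    stat = chi_squared(test_table.to_numpy())
    return counts, percentages, stat
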