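"""Mitochondrial-dynamics statistics over tracked time-lapse data.

Implements the capped window counting scheme (at most one fission-or-fusion
event per track per window, so three windows cap each track at 3 counted
events), the three-class track typology (balanced / fission-dominant /
fusion-dominant, with quiescent tracks reported separately), the
proportional fission-fusion difference, the Δ-fragmented series with its
trendline slope, and Pearson chi-squared contingency comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TRACK_CLASSES = ("balanced", "fission_dominant", "fusion_dominant", "quiescent")


@dataclass(frozen=True)
class WindowScheme:
    """Inclusive 1-based time-point windows, default (1,4), (4,7), (7,10).

    Consecutive windows share exactly their boundary time point, so the
    transition sets (1→2..3→4 | 4→5..6→7 | 7→8..9→10) partition cleanly; a
    transition indexed by left frame t belongs to the window with
    a ≤ t ≤ b−1.
    """

    windows: tuple[tuple[int, int], ...] = ((1, 4), (4, 7), (7, 10))

    def __post_init__(self) -> None:
        ws = tuple((int(a), int(b)) for a, b in self.windows)
        object.__setattr__(self, "windows", ws)
        if not ws:
            raise ValueError("need at least one window")
        for a, b in ws:
            if b < a + 1:
                raise ValueError(f"window ({a},{b}) must span at least 2 time points")
        for (a0, b0), (a1, b1) in zip(ws, ws[1:]):
            if a1 != b0:
                raise ValueError(
                    f"consecutive windows ({a0},{b0}) and ({a1},{b1}) must share "
                    "exactly their boundary time point"
                )

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_of_transition(self, t: int) -> int | None:
        """Index of the window containing transition t → t+1, or None."""
        for w, (a, b) in enumerate(self.windows):
            if a <= t <= b - 1:
                return w
        return None


@dataclass
class WindowSummary:
    """Per-track, per-window counted events plus raw multiplicities.

    ``table`` has one row per (track_id, window): ``counted`` in
    {"fission", "fusion", None}, ``raw_fissions``, ``raw_fusions``.
    """

    scheme: WindowScheme
    table: pd.DataFrame
    track_ids: tuple[int, ...]

    def counted_per_track(self) -> pd.DataFrame:
        """Counted fissions/fusions and totals per track (capped counting)."""
        rows = []
        for tid in self.track_ids:
            sub = self.table[self.table["track_id"] == tid]
            fis = int((sub["counted"] == "fission").sum())
            fus = int((sub["counted"] == "fusion").sum())
            rows.append({"track_id": tid, "fissions": fis, "fusions": fus,
                         "total": fis + fus})
        return pd.DataFrame(rows, columns=["track_id", "fissions", "fusions", "total"])


def window_events(
    tracks: pd.DataFrame,
    events: pd.DataFrame,
    scheme: WindowScheme = WindowScheme(),
) -> WindowSummary:
    """Count at most one event per track per window.

    When several events of a track fall in one window the earliest
    transition wins; at a tied transition fission is counted before fusion.
    This makes "maximum counted events = number of windows" an exact theorem
    of the counting rule.  Events at transitions outside every window are
    ignored with a logged warning.  Parent objects determine the event's
    track (parents and children share a track by construction).
    """
    track_of = {
        (int(f), int(i)): int(t)
        for f, i, t in zip(tracks["frame"], tracks["id"], tracks["track_id"])
    }
    track_ids = tuple(sorted(set(track_of.values())))
    # collect (track, window) -> list of (transition, kind)
    per_cell: dict[tuple[int, int], list[tuple[int, str]]] = {}
    for _, row in events.iterrows():
        t = int(row["transition"])
        w = scheme.window_of_transition(t)
        if w is None:
            logger.warning("event at transition %d lies outside every window; ignored", t)
            continue
        parent = (t, int(row["parents"][0]))
        if parent not in track_of:
            raise ValueError(f"event parent {parent} is not a tracked object")
        tid = track_of[parent]
        per_cell.setdefault((tid, w), []).append((t, row["kind"]))
    kind_order = {"fission": 0, "fusion": 1}
    rows = []
    for tid in track_ids:
        for w in range(scheme.n_windows):
            evs = sorted(per_cell.get((tid, w), []),
                         key=lambda e: (e[0], kind_order[e[1]]))
            rows.append({
                "track_id": tid,
                "window": w,
                "counted": evs[0][1] if evs else None,
                "raw_fissions": sum(1 for _, k in evs if k == "fission"),
                "raw_fusions": sum(1 for _, k in evs if k == "fusion"),
            })
    table = pd.DataFrame(rows, columns=["track_id", "window", "counted",
                                        "raw_fissions", "raw_fusions"])
    return WindowSummary(scheme, table, track_ids)


def classify_tracks(summary: WindowSummary) -> pd.DataFrame:
    """Assign each track one dynamics class from its capped counts.

    balanced ⇔ counted fissions = counted fusions ≥ 1; fission_dominant ⇔
    fissions > fusions; fusion_dominant ⇔ fissions < fusions; quiescent ⇔
    no counted events.
    """
    counts = summary.counted_per_track()
    def _cls(row):
        if row["total"] == 0:
            return "quiescent"
        if row["fissions"] > row["fusions"]:
            return "fission_dominant"
        if row["fissions"] < row["fusions"]:
            return "fusion_dominant"
        return "balanced"
    counts["track_class"] = counts.apply(_cls, axis=1)
    return counts


def class_proportions(classified: pd.DataFrame) -> dict:
    """Class tallies plus percentages over non-quiescent (active) tracks.

    The three reported classes partition only tracks that showed at least
    one counted event; quiescent tracks are tallied separately.
    """
    tallies = {c: int((classified["track_class"] == c).sum()) for c in TRACK_CLASSES}
    active = sum(tallies[c] for c in TRACK_CLASSES if c != "quiescent")
    percentages = {
        c: (100.0 * tallies[c] / active if active else float("nan"))
        for c in TRACK_CLASSES if c != "quiescent"
    }
    return {"tallies": tallies, "n_active": active, "percentages": percentages}


def proportional_difference(fissions: float, fusions: float,
                            mode: str = "proportional") -> float:
    """Fission preference index: (F − f)/(F + f) in [−1, 1] (positive = fission).

    ``mode="raw"`` returns the plain difference F − f instead.
    """
    if fissions < 0 or fusions < 0:
        raise ValueError("event counts must be non-negative")
    if mode == "raw":
        return float(fissions - fusions)
    if mode != "proportional":
        raise ValueError(f"unknown mode {mode!r}")
    total = fissions + fusions
    if total == 0:
        raise ValueError("proportional difference undefined for zero events")
    return float((fissions - fusions) / total)


@dataclass(frozen=True)
class FragmentedSeries:
    """Per-frame fragmented counts, their Δ series, and the trendline slope.

    Δ_k = count_{k+1} − count_k, so ΣΔ telescopes to last − first.  The
    slope is the OLS trendline of the Δ series against transition index.
    """

    counts: tuple[float, ...]
    delta: tuple[float, ...]
    slope: float


def delta_fragmented(counts) -> FragmentedSeries:
    """Consecutive differences of a per-frame fragmented-count series."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need a 1D series of at least 2 frames")
    delta = np.diff(counts)
    slope = trend_slope(delta) if delta.size >= 2 else float("nan")
    return FragmentedSeries(tuple(counts), tuple(delta), slope)


def trend_slope(series) -> float:
    """OLS slope of a series (or averaged per-cell series) against its index.

    A 2D input is interpreted as one series per cell (rows); rows are
    averaged point-wise before fitting, matching the convention of fitting
    the trendline to the across-cell average.  Sign convention downstream:
    positive = net drift toward fission.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 2:
        arr = arr.mean(axis=0)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need at least 2 points to fit a trendline")
    x = np.arange(arr.size)
    slope, _ = np.polyfit(x, arr, 1)
    return float(slope)


@dataclass(frozen=True)
class StatResult:
    """A chi-squared comparison: statistic, df, p-value and the table used."""

    statistic: float
    df: int
    p_value: float
    table: np.ndarray
    expected: np.ndarray

    def __post_init__(self) -> None:
        assert self.statistic >= 0 and 0 <= self.p_value <= 1


def chi_squared(table, yates: bool = False) -> StatResult:
    """Pearson chi-squared test of homogeneity on an r×c count table.

    Expected counts come from the row/column margins; df = (r−1)(c−1).  The
    continuity (Yates) correction is applied only when requested and only
    for 2×2 tables.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r×c table with r, c >= 2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("every row and column margin must be positive")
    correction = yates and arr.shape == (2, 2)
    stat, p, df, expected = stats.chi2_contingency(arr, correction=correction)
    return StatResult(float(stat), int(df), float(p), arr, expected)
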