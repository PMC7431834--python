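"""Clonal-mosaic statistics for marker-loss lineage analysis of GSCs.

Each mosaic germarium carries marker-negative (clonally marked, e.g.
GFP-negative) and marker-positive GSCs together with their fusome-counted
progeny.  Three statistics are computed:

* relative division rate — progeny per GSC of one lineage divided by
  progeny per GSC of the other within one germarium; a mock mosaic with
  identical lineages gives ≈ 1.0;
* maintenance — percentage of germaria retaining ≥ 1 marker-negative GSC
  at a given week;
* clone composition — among clone-bearing germaria, the split between
  partial clones (mixed GSC genotypes) and full clones (all GSCs
  marker-negative).

Only germaria with at least one GSC of each lineage and non-zero
denominator progeny enter the division-rate average; exclusions are logged
with their reason rather than coerced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ORIENTATIONS = ("neg_over_pos", "pos_over_neg")

COUNT_COLUMNS = ["germarium_id", "week", "gsc_neg", "gsc_pos", "prog_neg", "prog_pos"]


class ExcludedGermarium(ValueError):
    """A germarium fails the preconditions of the division-rate statistic."""


def relative_division_rate(
    gsc_neg: int, gsc_pos: int, prog_neg: int, prog_pos: int,
    orientation: str = "neg_over_pos",
) -> float:
    """Per-germarium relative division rate.

    With the default orientation the marker-negative lineage sits in the
    numerator: r = (prog_neg/gsc_neg) / (prog_pos/gsc_pos), so r < 1 means
    the marked clone divides slower.  Swapping orientation maps r to 1/r.

    Raises :class:`ExcludedGermarium` when a lineage has no GSC or the
    denominator lineage has zero progeny.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    if min(gsc_neg, gsc_pos, prog_neg, prog_pos) < 0:
        raise ValueError("counts must be non-negative")
    if gsc_neg == 0 or gsc_pos == 0:
        raise ExcludedGermarium("needs at least one GSC of each lineage")
    num = (prog_neg / gsc_neg, prog_pos / gsc_pos)
    if orientation == "pos_over_neg":
        num = num[::-1]
    if num[1] == 0:
        raise ExcludedGermarium("denominator lineage has zero progeny")
    return num[0] / num[1]


def division_rates(
    dataset: pd.DataFrame,
    orientation: str = "neg_over_pos",
    week: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-germarium division rates plus the exclusion log.

    Returns ``(rates, exclusions)``: rates with columns ``germarium_id,
    week, rate``; exclusions with ``germarium_id, week, reason``.
    """
    sub = dataset if week is None else dataset[dataset["week"] == week]
    rate_rows, excl_rows = [], []
    for _, row in sub.iterrows():
        try:
            r = relative_division_rate(
                int(row["gsc_neg"]), int(row["gsc_pos"]),
                int(row["prog_neg"]), int(row["prog_pos"]), orientation,
            )
            rate_rows.append({"germarium_id": row["germarium_id"],
                              "week": row["week"], "rate": r})
        except ExcludedGermarium as e:
            excl_rows.append({"germarium_id": row["germarium_id"],
                              "week": row["week"], "reason": str(e)})
    rates = pd.DataFrame(rate_rows, columns=["germarium_id", "week", "rate"])
    exclusions = pd.DataFrame(excl_rows, columns=["germarium_id", "week", "reason"])
    return rates, exclusions


def pooled_division_rate(
    dataset: pd.DataFrame,
    orientation: str = "neg_over_pos",
    week: int | None = None,
    aggregation: str = "mean",
) -> dict:
    """Aggregate the per-germarium rates.

    ``aggregation="mean"`` (default) averages per-germarium ratios and
    reports the SEM, matching per-germarium bar plots; ``"pooled"`` forms
    one ratio from summed counts of the included germaria.
    """
    rates, exclusions = division_rates(dataset, orientation, week)
    n = len(rates)
    if aggregation == "mean":
        value = float(rates["rate"].mean()) if n else float("nan")
        sem = float(rates["rate"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    elif aggregation == "pooled":
        sub = dataset if week is None else dataset[dataset["week"] == week]
        ok = sub[(sub["gsc_neg"] > 0) & (sub["gsc_pos"] > 0)]
        num = ok["prog_neg"].sum() / ok["gsc_neg"].sum()
        den = ok["prog_pos"].sum() / ok["gsc_pos"].sum()
        if orientation == "pos_over_neg":
            num, den = den, num
        value = float(num / den) if den else float("nan")
        sem = float("nan")
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return {"rate": value, "sem": sem, "n": n,
            "n_excluded": len(exclusions), "orientation": orientation}


def maintenance_percent(dataset: pd.DataFrame, week: int) -> float:
    """Percentage of germaria retaining ≥ 1 marker-negative GSC at ``week``."""
    sub = dataset[dataset["week"] == week]
    if len(sub) == 0:
        raise ValueError(f"no germaria observed at week {week}")
    return float(100.0 * (sub["gsc_neg"] >= 1).mean())


def clone_composition(dataset: pd.DataFrame, week: int) -> dict:
    """Partial- vs full-clone percentages among clone-bearing germaria.

    Clone-bearing: ≥ 1 marker-negative GSC.  Full clone: every GSC is
    marker-negative; partial: mixed genotypes.  The two percentages sum
    to 100.
    """
    sub = dataset[dataset["week"] == week]
    bearing = sub[sub["gsc_neg"] >= 1]
    if len(bearing) == 0:
        raise ValueError(f"no clone-bearing germaria at week {week}")
    full = (bearing["gsc_pos"] == 0).sum()
    partial = len(bearing) - full
    n = len(bearing)
    return {"partial_percent": 100.0 * partial / n,
            "full_percent": 100.0 * full / n,
            "n_clone_bearing": n}


@dataclass(frozen=True)
class ClonalSummary:
    """Per-week clonal statistics of one dataset."""

    orientation: str
    per_week: pd.DataFrame  # week, rate, sem, n, maintenance, partial %, full %


def summarize(dataset: pd.DataFrame, orientation: str = "neg_over_pos") -> ClonalSummary:
    """Division rate, maintenance, and clone composition for every week."""
    rows = []
    for week in sorted(dataset["week"].unique()):
        rate = pooled_division_rate(dataset, orientation, week)
        row = {"week": int(week), "rate": rate["rate"], "sem": rate["sem"],
               "n": rate["n"], "maintenance_percent": maintenance_percent(dataset, week)}
        try:
            comp = clone_composition(dataset, week)
            row.update(partial_percent=comp["partial_percent"],
                       full_percent=comp["full_percent"],
                       n_clone_bearing=comp["n_clone_bearing"])
        except ValueError:
            row.update(partial_percent=float("nan"), full_percent=float("nan"),
                       n_clone_bearing=0)
        rows.append(row)
    return ClonalSummary(orientation, pd.DataFrame(rows))
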