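"""Scoring detected segmentation/tracking output against scene ground truth.

Segmented objects are matched to true objects per frame by nearest centroid
(within a tolerance); detected events are then translated into true-id space
and compared with the generator's event log as (transition, kind, parents,
children) tuples, yielding event precision and recall.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import SceneGroundTruth


def match_objects(
    truth: SceneGroundTruth,
    objects: pd.DataFrame,
    max_distance_um: float = 1.0,
) -> dict[tuple[int, int], int]:
    """Map each detected (frame, label) to the nearest true object id.

    Matching is greedy nearest-centroid per frame; detections farther than
    ``max_distance_um`` from every true center stay unmatched.
    """
    mapping: dict[tuple[int, int], int] = {}
    for frame in sorted(objects["frame"].unique()):
        true_objs = truth.frames[int(frame) - 1]
        if not true_objs:
            continue
        centers = np.array([o.center for o in true_objs])
        ids = np.array([o.id for o in true_objs])
        sub = objects[objects["frame"] == frame]
        det = sub[["cz", "cy", "cx"]].to_numpy(dtype=float)
        for (_, row), point in zip(sub.iterrows(), det):
            dist = np.linalg.norm(centers - point, axis=1)
            k = int(np.argmin(dist))
            if dist[k] <= max_distance_um:
                mapping[(int(row["frame"]), int(row["id"]))] = int(ids[k])
    return mapping


def _event_keys(events: pd.DataFrame) -> set[tuple]:
    keys = set()
    for _, row in events.iterrows():
        keys.add((
            int(row["transition"]), row["kind"],
            frozenset(int(p) for p in row["parents"]),
            frozenset(int(c) for c in row["children"]),
        ))
    return keys


def score_events(
    truth: SceneGroundTruth,
    detected_events: pd.DataFrame,
    objects: pd.DataFrame,
    max_distance_um: float = 1.0,
) -> dict:
    """Event-level precision/recall of detected fissions/fusions vs the log.

    A detected event counts as correct only if its transition, kind, and the
    full sets of matched participant ids agree with a true event.
    """
    mapping = match_objects(truth, objects, max_distance_um)
    translated = []
    for _, row in detected_events.iterrows():
        t = int(row["transition"])
        parents = [mapping.get((t, int(p))) for p in row["parents"]]
        children = [mapping.get((t + 1, int(c))) for c in row["children"]]
        if None in parents or None in children:
            translated.append(None)  # unmatched participant: counts against precision
            continue
        translated.append((t, row["kind"], frozenset(parents), frozenset(children)))
    true_keys = _event_keys(truth.events_table())
    detected_keys = [k for k in translated if k is not None]
    hits = sum(1 for k in detected_keys if k in true_keys)
    recovered = len(true_keys & set(detected_keys))
    n_detected = len(translated)
    n_true = len(true_keys)
    return {
        "n_true": n_true,
        "n_detected": n_detected,
        "n_correct": hits,
        "precision": hits / n_detected if n_detected else float("nan"),
        "recall": recovered / n_true if n_true else float("nan"),
    }
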