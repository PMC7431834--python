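"""Overlap-based tracking of segmented mitochondria across adjacent frames.

Objects in adjacent time points are linked when their voxel masks share at
least ``min_overlap`` voxels; all linked objects share one track id
(connected components of the frame-object link graph).  A fission is an
object at *t* linked to ≥2 objects at *t+1*; a fusion is ≥2 objects at *t*
linked to one object at *t+1*.  Unlinked objects are deaths (at *t*) or
births (at *t+1*), not dynamics events.  Transitions are indexed by their
left frame, 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .segmentation import LabelVolume

EVENT_COLUMNS = ["transition", "kind", "parents", "children"]


@dataclass(frozen=True)
class FrameLink:
    """Voxel-overlap links for one transition t → t+1.

    ``pairs`` has columns ``src`` (object id at t), ``dst`` (object id at
    t+1) and ``overlap`` (shared voxels, each ≥ the minimum used).
    """

    transition: int
    pairs: pd.DataFrame


def link_adjacent(
    labels_t: LabelVolume,
    labels_t1: LabelVolume,
    min_overlap: int = 1,
) -> FrameLink:
    """Link objects of two adjacent frames by voxel-mask overlap.

    A pair (a, b) is recorded iff mask(a, t) and mask(b, t+1) share at least
    ``min_overlap`` voxels.
    """
    if labels_t.labels.shape != labels_t1.labels.shape:
        raise ValueError("label volumes must share the same grid shape")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    a, b = labels_t.labels, labels_t1.labels
    both = (a > 0) & (b > 0)
    if both.any():
        pairs, counts = np.unique(
            np.stack([a[both], b[both]]), axis=1, return_counts=True
        )
        keep = counts >= min_overlap
        df = pd.DataFrame({
            "src": pairs[0, keep], "dst": pairs[1, keep], "overlap": counts[keep],
        }).sort_values(["src", "dst"], ignore_index=True)
    else:
        df = pd.DataFrame(columns=["src", "dst", "overlap"]).astype(int)
    transition = labels_t.frame if labels_t.frame is not None else 0
    return FrameLink(transition, df)


def link_series(label_volumes: list[LabelVolume], min_overlap: int = 1) -> list[FrameLink]:
    """Link every adjacent pair of a label-volume series."""
    links = []
    for t in range(len(label_volumes) - 1):
        lv0, lv1 = label_volumes[t], label_volumes[t + 1]
        fl = link_adjacent(lv0, lv1, min_overlap)
        if lv0.frame is None:
            fl = FrameLink(t + 1, fl.pairs)
        links.append(fl)
    return links


def assign_track_ids(links: list[FrameLink], objects: pd.DataFrame) -> pd.DataFrame:
    """Partition all (frame, object) nodes into tracks.

    Track ids are connected components of the graph whose nodes are the
    objects of every frame and whose edges are the overlap links; an object
    with no links forms a singleton track.  Returns ``objects`` with a
    ``track_id`` column added (ids 1..K, ordered by first appearance).
    """
    g = nx.Graph()
    g.add_nodes_from(zip(objects["frame"].astype(int), objects["id"].astype(int)))
    for fl in links:
        t = fl.transition
        for src, dst in zip(fl.pairs["src"], fl.pairs["dst"]):
            u, v = (t, int(src)), (t + 1, int(dst))
            if u not in g or v not in g:
                raise ValueError(f"link {u}->{v} references an unknown object")
            g.add_edge(u, v)
    components = sorted(nx.connected_components(g), key=min)
    node_to_track = {}
    for tid, comp in enumerate(components, start=1):
        for node in comp:
            node_to_track[node] = tid
    out = objects.copy()
    out["track_id"] = [
        node_to_track[(int(f), int(i))] for f, i in zip(out["frame"], out["id"])
    ]
    return out


def detect_events(
    links: list[FrameLink],
    objects: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive fission/fusion events (and births/deaths) from overlap links.

    Per transition: an object at *t* with out-degree d ≥ 2 yields one
    fission with its d children; an object at *t+1* with in-degree d ≥ 2
    yields one fusion with its d parents.  One-to-one links yield nothing.
    If ``objects`` is given, objects untouched by any link are reported as
    births/deaths (second return value); they are not dynamics events.

    Returns ``(events, appearances)``: events with columns ``transition,
    kind, parents, children`` (id tuples) and appearances with ``frame, id,
    change`` (``birth``/``death``).
    """
    event_rows = []
    linked_src: dict[int, set[int]] = {}
    linked_dst: dict[int, set[int]] = {}
    for fl in links:
        t = fl.transition
        linked_src.setdefault(t, set()).update(int(s) for s in fl.pairs["src"])
        linked_dst.setdefault(t + 1, set()).update(int(d) for d in fl.pairs["dst"])
        by_src = fl.pairs.groupby("src")["dst"]
        for src, dsts in by_src:
            if len(dsts) >= 2:
                event_rows.append({
                    "transition": t, "kind": "fission",
                    "parents": (int(src),),
                    "children": tuple(sorted(int(d) for d in dsts)),
                })
        by_dst = fl.pairs.groupby("dst")["src"]
        for dst, srcs in by_dst:
            if len(srcs) >= 2:
                event_rows.append({
                    "transition": t, "kind": "fusion",
                    "parents": tuple(sorted(int(s) for s in srcs)),
                    "children": (int(dst),),
                })
    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    if events.shape[0]:
        events = events.sort_values(["transition", "kind"], ignore_index=True)

    appearance_rows = []
    if objects is not None and len(links) > 0:
        frames = sorted(objects["frame"].astype(int).unique())
        by_frame = {f: set(objects.loc[objects["frame"] == f, "id"].astype(int))
                    for f in frames}
        transitions = {fl.transition for fl in links}
        for f in frames:
            if f in transitions:  # not the last frame: unlinked-out = death
                for oid in sorted(by_frame[f] - linked_src.get(f, set())):
                    appearance_rows.append({"frame": f, "id": oid, "change": "death"})
            if (f - 1) in transitions:  # not the first frame: unlinked-in = birth
                for oid in sorted(by_frame[f] - linked_dst.get(f, set())):
                    appearance_rows.append({"frame": f, "id": oid, "change": "birth"})
    appearances = pd.DataFrame(appearance_rows, columns=["frame", "id", "change"])
    return events, appearances


def track_scene(
    label_volumes: list[LabelVolume],
    objects: pd.DataFrame,
    min_overlap: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience: link a series, assign tracks and detect events in one call."""
    links = link_series(label_volumes, min_overlap)
    tracked = assign_track_ids(links, objects)
    events, appearances = detect_events(links, objects)
    return tracked, events, appearances
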