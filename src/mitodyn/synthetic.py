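"""Ground-truthed synthetic data for every stage of the pipeline.

Three generators:

* :func:`generate_scene` / :func:`render_frame` — 4D scenes of ellipsoidal
  mitochondria undergoing a scheduled or stochastic fission/fusion program,
  rendered with photobleaching, optional blur and shot noise.  The generator
  keeps the exact object trajectories and event log
  (:class:`SceneGroundTruth`), which is the oracle for tracking accuracy.
* :func:`generate_tem_population` — 2D section morphometry records (area,
  W/H ratio) with controllable means and dispersions.
* :func:`simulate_mosaic` — mosaic germaria with two genetically marked GSC
  lineages, configurable division rates and weekly loss hazards; the null
  model behind the clonal-mosaic statistics.

All randomness flows from the seed in each config; sub-streams are derived
deterministically, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import FRAGMENTED_VOLUME_UM3, ImageStack


class ScheduleError(ValueError):
    """A scene event schedule references dead/missing objects or bad frames."""


# ---------------------------------------------------------------------------
# scene configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduledEvent:
    """One scheduled dynamics event at transition ``transition`` → ``transition+1``.

    ``transition`` is 1-based and indexed by its left frame.  ``targets``
    names the participating object id(s); a fission with ``targets=None``
    picks a random living object at run time.
    """

    transition: int
    kind: str  # "fission" | "fusion"
    targets: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fission", "fusion"):
            raise ScheduleError(f"unknown event kind {self.kind!r}")
        if self.targets is not None:
            object.__setattr__(self, "targets", tuple(int(t) for t in self.targets))
            n = len(self.targets)
            if self.kind == "fission" and n != 1:
                raise ScheduleError(f"fission takes exactly one target, got {self.targets}")
            if self.kind == "fusion" and n != 2:
                raise ScheduleError(f"fusion takes exactly two targets, got {self.targets}")


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, motion and event program of one synthetic GSC-like scene.

    Defaults emulate the live-imaging regime analysed here: an initial pool
    of ~69 mitochondria (the young-GSC count at time 0), 10 analysed time
    points at ~2 s intervals, sub-resolution Brownian jitter, and ellipsoids
    of ~0.09 μm³ whose fission products straddle the 0.05 μm³ fragmentation
    threshold.
    """

    shape: tuple[int, int, int] = (96, 96, 96)          # voxels, (z, y, x)
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)  # μm
    n_frames: int = 10
    n_objects: int = 69
    semiaxes_um: tuple[float, float, float] = (0.35, 0.28, 0.22)
    semiaxes_cv: float = 0.12            # relative spread of per-object semi-axes
    displacement_um: float = 0.04        # per-axis Gaussian step per frame
    events: tuple[ScheduledEvent, ...] = ()
    fission_prob: float = 0.0            # per object per transition
    fusion_prob: float = 0.0             # per object per transition (paired by proximity)
    split_range: tuple[float, float] = (0.3, 0.7)  # fission volume fraction to child 1
    doublet_gap_um: float = 0.25         # surface gap of pre-fusion partners / new siblings
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("a scene needs at least 2 frames")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.n_objects < 1:
            raise ValueError("need at least one initial object")
        lo, hi = self.split_range
        if not (0 < lo <= hi < 1):
            raise ValueError("split_range must satisfy 0 < lo <= hi < 1")
        object.__setattr__(self, "events", tuple(self.events))
        for ev in self.events:
            if not (1 <= ev.transition <= self.n_frames - 1):
                raise ScheduleError(
                    f"event {ev} lies outside transitions 1..{self.n_frames - 1}"
                )

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))


@dataclass(frozen=True)
class OpticsConfig:
    """Rendering model: intensities, blur, shot noise, photobleaching.

    Foreground intensity decays as ``exp(-bleach_rate · (frame - 1))``,
    emulating the bleaching that per-frame mean normalization later corrects.
    """

    background: float = 10.0
    foreground: float = 200.0
    blur_sigma_um: float = 0.0
    shot_noise: bool = False
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.background < 0 or self.foreground < 0:
            raise ValueError("intensity levels must be non-negative")
        if self.bleach_rate < 0 or self.blur_sigma_um < 0:
            raise ValueError("bleach rate and blur must be non-negative")


@dataclass(frozen=True)
class TrueObject:
    """One axis-aligned ellipsoidal mitochondrion at one frame."""

    id: int
    center: tuple[float, float, float]    # μm, (z, y, x)
    semiaxes: tuple[float, float, float]  # μm

    @property
    def volume(self) -> float:
        a, b, c = self.semiaxes
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass
class SceneGroundTruth:
    """True trajectories and event log of a generated scene."""

    config: SceneConfig
    frames: list[list[TrueObject]]               # frames[k] = objects at frame k+1
    events: pd.DataFrame                         # transition, kind, parents, children

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def counts(self) -> np.ndarray:
        """True object count per frame."""
        return np.array([len(f) for f in self.frames])

    def fragmented_counts(self, threshold: float = FRAGMENTED_VOLUME_UM3) -> np.ndarray:
        """True fragmented count per frame under a volume threshold (strict <)."""
        return np.array(
            [sum(1 for o in f if o.volume < threshold) for f in self.frames]
        )

    def objects_table(self) -> pd.DataFrame:
        rows = []
        for k, objs in enumerate(self.frames, start=1):
            for o in objs:
                rows.append({
                    "frame": k, "id": o.id,
                    "cz": o.center[0], "cy": o.center[1], "cx": o.center[2],
                    "sz": o.semiaxes[0], "sy": o.semiaxes[1], "sx": o.semiaxes[2],
                    "volume_um3": o.volume,
                })
        return pd.DataFrame(rows)

    def events_table(self) -> pd.DataFrame:
        return self.events.copy()


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into [lo, hi] (single bounce is enough for small steps)."""
    if hi <= lo:
        return 0.5 * (lo + hi)
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
    return x


def _place_initial(config: SceneConfig, rng: np.random.Generator,
                   doublet_pairs: list[tuple[int, int]]) -> list[TrueObject]:
    """Jittered-grid placement; pre-fusion partners sit as adjacent doublets."""
    extent = np.array(config.extent_um)
    partners = {b: a for a, b in doublet_pairs}
    n_sites_needed = config.n_objects - len(doublet_pairs)
    per_axis = max(2, math.ceil(n_sites_needed ** (1 / 3)))
    spacing = extent / per_axis
    sites = np.array([
        ((i + 0.5) * spacing[0], (j + 0.5) * spacing[1], (k + 0.5) * spacing[2])
        for i in range(per_axis) for j in range(per_axis) for k in range(per_axis)
    ])
    rng.shuffle(sites)
    jitter = 0.1  # μm
    objects: dict[int, TrueObject] = {}
    site_iter = iter(sites)
    for oid in range(config.n_objects):
        semis = tuple(
            max(1.2 * max(config.voxel_size),
                s * (1 + config.semiaxes_cv * rng.standard_normal()))
            for s in config.semiaxes_um
        )
        if oid in partners:
            # sit next to the already-placed partner along a random axis
            a = objects[partners[oid]]
            axis = int(rng.integers(3))
            offset = a.semiaxes[axis] + semis[axis] + config.doublet_gap_um
            center = list(a.center)
            center[axis] += offset
        else:
            site = next(site_iter)
            center = [site[d] + jitter * rng.standard_normal() for d in range(3)]
        center = tuple(
            _reflect(center[d], semis[d] + config.voxel_size[d],
                     extent[d] - semis[d] - config.voxel_size[d])
            for d in range(3)
        )
        objects[oid] = TrueObject(oid, center, semis)
    return [objects[i] for i in range(config.n_objects)]


def _fission_children(parent: TrueObject, u: float, axis: int, gap: float,
                      next_id: int) -> tuple[TrueObject, TrueObject]:
    """Split a parent into two children conserving total volume exactly."""
    f1, f2 = u ** (1 / 3), (1 - u) ** (1 / 3)
    s1 = tuple(s * f1 for s in parent.semiaxes)
    s2 = tuple(s * f2 for s in parent.semiaxes)
    c1 = list(parent.center)
    c2 = list(parent.center)
    c1[axis] -= gap / 2 + s1[axis]
    c2[axis] += gap / 2 + s2[axis]
    return (TrueObject(next_id, tuple(c1), s1),
            TrueObject(next_id + 1, tuple(c2), s2))


def _fusion_child(a: TrueObject, b: TrueObject, next_id: int) -> TrueObject:
    """Merge two parents into one child conserving volume, elongated to span both."""
    va, vb = a.volume, b.volume
    v = va + vb
    center = tuple((va * ca + vb * cb) / v for ca, cb in zip(a.center, b.center))
    d = np.array(b.center) - np.array(a.center)
    axis = int(np.argmax(np.abs(d)))
    # long semi-axis covers both parent centers so overlap tracking sees both
    half_span = abs(d[axis]) / 2 + 0.6 * min(a.semiaxes[axis], b.semiaxes[axis])
    long = max(half_span, 1e-6)
    trans = math.sqrt(v / (4.0 / 3.0 * math.pi * long))
    semis = [trans, trans, trans]
    semis[axis] = long
    return TrueObject(next_id, center, tuple(semis))


def generate_scene(config: SceneConfig) -> SceneGroundTruth:
    """Simulate object trajectories and the fission/fusion program of one scene.

    Guarantees: count conservation against the event log, exact volume
    conservation at every event, reflecting boundaries (objects never leave
    the grid), and full determinism given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    extent = np.array(config.extent_um)

    # scheduled fusions between *initial* objects start life as doublets
    doublet_pairs = [
        tuple(sorted(ev.targets)) for ev in config.events
        if ev.kind == "fusion" and ev.targets is not None
        and all(t < config.n_objects for t in ev.targets)
    ]
    for a, b in doublet_pairs:
        if a == b:
            raise ScheduleError(f"fusion of object {a} with itself")
    paired: dict[int, int] = {}
    fused_away: set[int] = set()
    for a, b in doublet_pairs:
        paired[a] = b
        paired[b] = a

    alive = {o.id: o for o in _place_initial(config, rng, doublet_pairs)}
    next_id = config.n_objects
    frames: list[list[TrueObject]] = [sorted(alive.values(), key=lambda o: o.id)]
    event_rows: list[dict] = []

    schedule: dict[int, list[ScheduledEvent]] = {}
    for ev in config.events:
        schedule.setdefault(ev.transition, []).append(ev)

    for t in range(1, config.n_frames):
        # --- events at transition t -> t+1 -------------------------------
        todo = [(ev, False) for ev in schedule.get(t, [])]
        # stochastic program: per-object fission / proximity-paired fusion
        stochastic_targets: set[int] = set()
        if config.fission_prob > 0:
            for oid in sorted(alive):
                if rng.random() < config.fission_prob:
                    todo.append((ScheduledEvent(t, "fission", (oid,)), True))
                    stochastic_targets.add(oid)
        if config.fusion_prob > 0 and len(alive) >= 2:
            marked = [oid for oid in sorted(alive)
                      if oid not in stochastic_targets
                      and rng.random() < config.fusion_prob]
            while len(marked) >= 2:
                a = marked.pop(0)
                centers = {m: np.array(alive[m].center) for m in marked}
                b = min(marked, key=lambda m: np.linalg.norm(centers[m] - alive[a].center))
                marked.remove(b)
                todo.append((ScheduledEvent(t, "fusion", (a, b)), True))
        consumed: set[int] = set()
        for ev, stochastic in todo:
            if ev.kind == "fission":
                if ev.targets is None:
                    candidates = [oid for oid in sorted(alive)
                                  if oid not in consumed and oid not in paired]
                    if not candidates:
                        continue
                    target = int(rng.choice(candidates))
                else:
                    (target,) = ev.targets
                if target not in alive or target in consumed:
                    if stochastic:
                        continue
                    raise ScheduleError(
                        f"fission at transition {t} targets object {target}, "
                        "which is not alive"
                    )
                parent = alive.pop(target)
                consumed.add(target)
                u = rng.uniform(*config.split_range)
                axis = int(rng.integers(3))
                c1, c2 = _fission_children(parent, u, axis,
                                           config.doublet_gap_um, next_id)
                next_id += 2
                alive[c1.id] = c1
                alive[c2.id] = c2
                event_rows.append({"transition": t, "kind": "fission",
                                   "parents": (parent.id,),
                                   "children": (c1.id, c2.id)})
            else:
                if ev.targets is None:
                    raise ScheduleError(
                        f"stochastic fusion at transition {t} lost its targets"
                    )
                a_id, b_id = ev.targets
                if len(alive) < 2:
                    if stochastic:
                        continue
                    raise ScheduleError(
                        f"fusion at transition {t} needs >=2 living objects"
                    )
                missing = [x for x in (a_id, b_id) if x not in alive or x in consumed]
                if missing:
                    if stochastic:
                        continue
                    raise ScheduleError(
                        f"fusion at transition {t} targets dead object(s) {missing}"
                    )
                a, b = alive.pop(a_id), alive.pop(b_id)
                consumed.update((a_id, b_id))
                fused_away.update((a_id, b_id))
                child = _fusion_child(a, b, next_id)
                next_id += 1
                alive[child.id] = child
                event_rows.append({"transition": t, "kind": "fusion",
                                   "parents": (a_id, b_id),
                                   "children": (child.id,)})

        # --- Brownian motion with reflecting boundaries ------------------
        steps: dict[int, np.ndarray] = {}
        for oid in sorted(alive):
            mate = paired.get(oid)
            if (mate is not None and mate in alive and mate not in fused_away
                    and mate in steps):
                steps[oid] = steps[mate]  # doublets drift together until fused
            else:
                steps[oid] = rng.normal(0.0, config.displacement_um, size=3)
        moved = {}
        for oid in sorted(alive):
            o = alive[oid]
            center = tuple(
                _reflect(o.center[d] + steps[oid][d],
                         o.semiaxes[d] + config.voxel_size[d],
                         extent[d] - o.semiaxes[d] - config.voxel_size[d])
                for d in range(3)
            )
            moved[oid] = TrueObject(oid, center, o.semiaxes)
        alive = moved
        frames.append(sorted(alive.values(), key=lambda o: o.id))

    events = pd.DataFrame(event_rows, columns=["transition", "kind", "parents", "children"])
    truth = SceneGroundTruth(config, frames, events)
    _check_conservation(truth)
    return truth


def _check_conservation(truth: SceneGroundTruth) -> None:
    """Assert N(t+1) = N(t) + Σ(children−1, fissions) − Σ(parents−1, fusions)."""
    counts = truth.counts()
    for t in range(1, truth.n_frames):
        ev = truth.events[truth.events["transition"] == t]
        delta = 0
        for _, row in ev.iterrows():
            if row["kind"] == "fission":
                delta += len(row["children"]) - 1
            else:
                delta -= len(row["parents"]) - 1
        if counts[t] != counts[t - 1] + delta:
            raise AssertionError(
                f"count conservation violated at transition {t}: "
                f"{counts[t - 1]} + {delta} != {counts[t]}"
            )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_frame(
    truth: SceneGroundTruth,
    frame: int,
    optics: OpticsConfig = OpticsConfig(),
    rng: np.random.Generator | None = None,
) -> ImageStack:
    """Rasterize one frame of a scene into an intensity stack.

    ``frame`` is 1-based.  Voxels whose centers fall inside any true
    ellipsoid get ``foreground · exp(-bleach_rate·(frame-1))``, all others
    the background level; then optional Gaussian blur and Poisson shot
    noise.  Noise is seeded from the scene seed and frame index when no
    ``rng`` is supplied, so rendering is deterministic.
    """
    if not (1 <= frame <= truth.n_frames):
        raise ValueError(f"frame {frame} outside 1..{truth.n_frames}")
    config = truth.config
    vs = np.array(config.voxel_size)
    data = np.full(config.shape, float(optics.background))
    fg = optics.foreground * math.exp(-optics.bleach_rate * (frame - 1))
    voxel_min = min(config.voxel_size)
    for o in truth.frames[frame - 1]:
        if min(o.semiaxes) < voxel_min / 2:
            warnings.warn(
                f"object {o.id} at frame {frame} is smaller than one voxel "
                "and may be unrecoverable", stacklevel=2,
            )
        lo = [max(0, int((o.center[d] - o.semiaxes[d]) / vs[d]) - 1) for d in range(3)]
        hi = [min(config.shape[d], int((o.center[d] + o.semiaxes[d]) / vs[d]) + 2)
              for d in range(3)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        grids = np.meshgrid(
            *[(np.arange(lo[d], hi[d]) + 0.5) * vs[d] for d in range(3)],
            indexing="ij",
        )
        q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, o.center, o.semiaxes))
        box = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        box[q <= 1.0] = fg
    if optics.blur_sigma_um > 0:
        data = ndimage.gaussian_filter(data, sigma=optics.blur_sigma_um / vs)
    if optics.shot_noise:
        if rng is None:
            rng = np.random.default_rng((config.seed * 1_000 + frame) % (2**31))
        data = rng.poisson(np.maximum(data, 0)).astype(float)
    return ImageStack(data, config.voxel_size, frame)


def render_scene(
    truth: SceneGroundTruth,
    optics: OpticsConfig = OpticsConfig(),
) -> list[ImageStack]:
    """Render every frame of a scene."""
    return [render_frame(truth, k, optics) for k in range(1, truth.n_frames + 1)]


# ---------------------------------------------------------------------------
# 2D TEM-style section populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphPopConfig:
    """Population of 2D mitochondrial profiles: (area, W/H ratio) records.

    Defaults reproduce the young-GSC reference sample used to anchor the
    three-class morphology scheme: mean area 0.11 μm² (SD 0.11) and mean W/H
    2.34 (SD 1.9).
    """

    n: int = 177
    area_mean: float = 0.11       # μm²
    area_sd: float = 0.11
    ratio_mean: float = 2.34      # W/H, ≥ 1
    ratio_sd: float = 1.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.area_mean <= 0 or self.ratio_mean < 1:
            raise ValueError("area mean must be > 0 and ratio mean >= 1")
        if self.area_sd < 0 or self.ratio_sd < 0:
            raise ValueError("dispersions must be non-negative")


def _gamma_sample(rng, mean: float, sd: float, n: int) -> np.ndarray:
    """Gamma variates with the exact requested mean; sd 0 degenerates to the mean."""
    if sd == 0:
        return np.full(n, mean)
    shape = (mean / sd) ** 2
    return rng.gamma(shape, scale=sd**2 / mean, size=n)


def generate_tem_population(config: MorphPopConfig) -> pd.DataFrame:
    """Sample (area, ratio) records: Gamma areas, shifted-Gamma ratios ≥ 1."""
    rng = np.random.default_rng(config.seed)
    areas = _gamma_sample(rng, config.area_mean, config.area_sd, config.n)
    ratios = 1.0 + _gamma_sample(rng, config.ratio_mean - 1.0, config.ratio_sd, config.n)
    return pd.DataFrame({
        "id": np.arange(config.n),
        "area_um2": areas,
        "ratio": ratios,
    })


# ---------------------------------------------------------------------------
# mosaic germaria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MosaicConfig:
    """Mosaic-germarium simulator: two GSC lineages per germarium.

    Lineage "neg" is the marker-negative (clonally marked) lineage, "pos"
    the marker-positive one.  Each week every GSC is lost independently with
    its lineage's hazard; each surviving GSC then shows ``progeny_rate``
    fusome-marked progeny units with small integer jitter
    (variance ``progeny_dispersion``) — GSC divisions are cell-cycle-clocked,
    so progeny counts over a fixed observation are tightly regulated rather
    than Poisson-dispersed.
    """

    n_germaria: int = 500
    gsc_neg: int = 2
    gsc_pos: int = 2
    progeny_rate_neg: float = 6.0
    progeny_rate_pos: float = 6.0
    progeny_dispersion: float = 1.0      # variance of the per-GSC jitter
    loss_hazard_neg: float = 0.025       # per GSC per week
    loss_hazard_pos: float = 0.025
    weeks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_germaria < 1:
            raise ValueError("need at least one germarium")
        if self.progeny_rate_neg < 0 or self.progeny_rate_pos < 0:
            raise ValueError("progeny rates must be non-negative")
        for h in (self.loss_hazard_neg, self.loss_hazard_pos):
            if not (0 <= h <= 1):
                raise ValueError("loss hazards must lie in [0, 1]")
        if self.weeks < 1:
            raise ValueError("need at least one observation week")


def _progeny(rng, n_gsc: int, rate: float, dispersion: float) -> int:
    if n_gsc == 0:
        return 0
    jitter = rng.normal(0.0, math.sqrt(dispersion), size=n_gsc) if dispersion > 0 else 0.0
    counts = np.maximum(0, np.rint(rate + jitter)).astype(int)
    return int(np.sum(counts))


def simulate_mosaic(config: MosaicConfig) -> pd.DataFrame:
    """Simulate per-germarium clonal counts over the observation weeks.

    Returns one row per germarium per week: ``germarium_id, week, gsc_neg,
    gsc_pos, prog_neg, prog_pos``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for g in range(config.n_germaria):
        n_neg, n_pos = config.gsc_neg, config.gsc_pos
        for week in range(1, config.weeks + 1):
            n_neg = int(np.sum(rng.random(n_neg) >= config.loss_hazard_neg)) if n_neg else 0
            n_pos = int(np.sum(rng.random(n_pos) >= config.loss_hazard_pos)) if n_pos else 0
            rows.append({
                "germarium_id": g,
                "week": week,
                "gsc_neg": n_neg,
                "gsc_pos": n_pos,
                "prog_neg": _progeny(rng, n_neg, config.progeny_rate_neg,
                                     config.progeny_dispersion),
                "prog_pos": _progeny(rng, n_pos, config.progeny_rate_pos,
                                     config.progeny_dispersion),
            })
    return pd.DataFrame(rows)
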