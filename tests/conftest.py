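"""Shared fixtures: a seeded scene with a known event program, rendered
noiselessly and with shot noise, pushed through the full
segment→track→detect pipeline once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitodyn.evaluate import score_events
from mitodyn.segmentation import segment_series
from mitodyn.synthetic import (OpticsConfig, SceneConfig, ScheduledEvent,
                               generate_scene, render_scene)
from mitodyn.tracking import track_scene

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: 50 objects over 10 frames with 5 scheduled fissions and 3 scheduled fusions.
RECOVERY_EVENTS = (
    ScheduledEvent(2, "fission", (0,)),
    ScheduledEvent(3, "fusion", (44, 45)),
    ScheduledEvent(4, "fission", (1,)),
    ScheduledEvent(5, "fission", (3,)),
    ScheduledEvent(6, "fission", (2,)),
    ScheduledEvent(7, "fusion", (46, 47)),
    ScheduledEvent(8, "fission", (4,)),
    ScheduledEvent(8, "fusion", (48, 49)),
)


def make_recovery_config(seed: int = 7) -> SceneConfig:
    return SceneConfig(n_objects=50, n_frames=10, seed=seed, events=RECOVERY_EVENTS)


def run_tracking_pipeline(truth, optics: OpticsConfig):
    stacks = render_scene(truth, optics)
    label_volumes, objects = segment_series(stacks, low=50.0, high=120.0)
    tracked, events, appearances = track_scene(label_volumes, objects)
    return {
        "truth": truth,
        "stacks": stacks,
        "label_volumes": label_volumes,
        "objects": objects,
        "tracked": tracked,
        "events": events,
        "appearances": appearances,
        "scores": score_events(truth, events, objects),
    }


@pytest.fixture(scope="session")
def noiseless_bundle():
    truth = generate_scene(make_recovery_config())
    return run_tracking_pipeline(truth, OpticsConfig(shot_noise=False))


@pytest.fixture(scope="session")
def noisy_bundle():
    truth = generate_scene(make_recovery_config())
    return run_tracking_pipeline(
        truth, OpticsConfig(shot_noise=True, blur_sigma_um=0.05)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
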