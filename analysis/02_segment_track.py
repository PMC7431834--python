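#!/usr/bin/env python
"""Segment the rendered scene (bleach correction + hysteresis thresholding),
track objects by voxel overlap, detect fission/fusion events, and score them
against the simulator's event log.

Reads results/scene/, writes results/tracking/: objects.csv, tracks.csv,
events.csv, appearances.csv, recovery.json.
"""

import json
from pathlib import Path

from mitodyn import io
from mitodyn.evaluate import score_events
from mitodyn.segmentation import segment_series
from mitodyn.synthetic import SceneConfig, generate_scene
from mitodyn.tracking import track_scene

SCENE = Path("results/scene")
OUT = Path("results/tracking")


def main() -> None:
    # ground truth is regenerated from the config echoed by the simulate step
    import yaml
    payload = yaml.safe_load((SCENE / "scene_config.yaml").read_text())
    payload.pop("config_hash", None)
    from mitodyn.synthetic import ScheduledEvent
    payload["events"] = tuple(
        ScheduledEvent(e["transition"], e["kind"],
                       tuple(e["targets"]) if e["targets"] else None)
        for e in payload["events"]
    )
    for key in ("shape", "voxel_size", "semiaxes_um", "split_range"):
        payload[key] = tuple(payload[key])
    config = SceneConfig(**payload)
    truth = generate_scene(config)

    stacks = io.load_stack_series(SCENE, config.voxel_size)
    label_volumes, objects = segment_series(stacks, low=50.0, high=120.0)
    tracked, events, appearances = track_scene(label_volumes, objects)
    scores = score_events(truth, events, objects)

    OUT.mkdir(parents=True, exist_ok=True)
    io.save_table(objects, OUT / "objects.csv")
    io.save_table(tracked, OUT / "tracks.csv")
    io.save_table(events, OUT / "events.csv")
    io.save_table(appearances, OUT / "appearances.csv")
    io.save_report(scores, OUT / "recovery.json")

    per_frame = [int((objects["frame"] == f).sum()) for f in range(1, len(stacks) + 1)]
    print(f"segmented objects per frame: {per_frame}")
    print(f"detected {len(events)} events "
          f"({int((events['kind'] == 'fission').sum())} fissions, "
          f"{int((events['kind'] == 'fusion').sum())} fusions)")
    print("recovery vs ground truth: "
          + json.dumps({k: round(v, 3) if isinstance(v, float) else v
                        for k, v in scores.items()}))


if __name__ == "__main__":
    main()
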