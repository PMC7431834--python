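"""End-to-end pipeline configuration with up-front validation.

All numeric parameters are checked against the preconditions of the module
that consumes them *before* any stage runs, so a bad threshold fails fast
with the offending field named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import WindowScheme
from .morphology import MorphologyThresholds
from .segmentation import FRAGMENTED_VOLUME_UM3


@dataclass
class PipelineConfig:
    """Parameters of a full simulate→segment→track→stats run."""

    out_dir: str = "results/pipeline"
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    low_threshold: float = 50.0
    high_threshold: float = 120.0
    connectivity: int = 26
    min_overlap: int = 1
    frag_threshold_um3: float = FRAGMENTED_VOLUME_UM3
    windows: tuple[tuple[int, int], ...] = ((1, 4), (4, 7), (7, 10))
    morph_area_um2: float = 0.11
    morph_ratio: float = 2.34
    orientation: str = "neg_over_pos"
    n_frames: int = 10
    n_objects: int = 69
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errors = []
        if any(v <= 0 for v in self.voxel_size):
            errors.append("voxel_size: all entries must be positive")
        if self.low_threshold < 0:
            errors.append("low_threshold: must be non-negative")
        if self.low_threshold > self.high_threshold:
            errors.append("low_threshold: must not exceed high_threshold")
        if self.min_overlap < 1:
            errors.append("min_overlap: must be >= 1")
        if self.frag_threshold_um3 < 0:
            errors.append("frag_threshold_um3: must be non-negative")
        if self.n_frames < 2:
            errors.append("n_frames: must be >= 2")
        if self.orientation not in ("neg_over_pos", "pos_over_neg"):
            errors.append("orientation: must be neg_over_pos or pos_over_neg")
        try:
            WindowScheme(self.windows)
        except ValueError as e:
            errors.append(f"windows: {e}")
        try:
            MorphologyThresholds(self.morph_area_um2, self.morph_ratio)
        except ValueError as e:
            errors.append(f"morphology thresholds: {e}")
        if errors:
            raise ValueError("invalid pipeline configuration: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.pop("config_hash", None)
        if "voxel_size" in payload:
            payload["voxel_size"] = tuple(payload["voxel_size"])
        if "windows" in payload:
            payload["windows"] = tuple(tuple(w) for w in payload["windows"])
        return cls(**payload)
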