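"""File formats of the pipeline: multi-page TIFF stacks, CSV tables, configs.

Conventions: one TIFF per time point (``frame_%04d.tif``), comma-separated
UTF-8 CSV with a mandatory header and floats at 6 significant digits,
event participant id tuples serialized "|"-joined.  Time points are 1-based
in every file on disk; voxel indices are 0-based in memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import ImageStack, LabelVolume

FRAME_PATTERN = "frame_%04d.tif"
LABEL_PATTERN = "labels_%04d.tif"


def save_stack(stack: ImageStack, path: Path) -> None:
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")


def load_stack(path: Path, voxel_size, frame: int | None = None) -> ImageStack:
    return ImageStack(tifffile.imread(path), tuple(voxel_size), frame)


def save_stack_series(stacks: list[ImageStack], out_dir: Path,
                      pattern: str = FRAME_PATTERN) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, stack in enumerate(stacks, start=1):
        p = out_dir / (pattern % k)
        save_stack(stack, p)
        paths.append(p)
    return paths


def load_stack_series(in_dir: Path, voxel_size,
                      pattern: str = FRAME_PATTERN) -> list[ImageStack]:
    in_dir = Path(in_dir)
    stacks = []
    k = 1
    while (p := in_dir / (pattern % k)).exists():
        stacks.append(load_stack(p, voxel_size, frame=k))
        k += 1
    if not stacks:
        raise FileNotFoundError(f"no frames matching {pattern!r} under {in_dir}")
    return stacks


def save_labels(labels: LabelVolume, path: Path) -> None:
    tifffile.imwrite(path, labels.labels.astype(np.int32), photometric="minisblack")


def load_labels(path: Path, voxel_size, frame: int | None = None) -> LabelVolume:
    return LabelVolume(tifffile.imread(path).astype(np.int64), tuple(voxel_size), frame)


def save_table(df: pd.DataFrame, path: Path) -> None:
    """CSV with "|"-joined id tuples and 6-significant-digit floats."""
    df = df.copy()
    for col in ("parents", "children"):
        if col in df.columns:
            df[col] = df[col].map(lambda t: "|".join(str(int(x)) for x in t))
    df.to_csv(path, index=False, float_format="%.6g")


def load_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("parents", "children"):
        if col in df.columns:
            df[col] = df[col].map(
                lambda s: tuple(int(x) for x in str(s).split("|"))
            )
    return df


def config_hash(config) -> str:
    """Stable short hash of a (dataclass or dict) configuration."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def save_config(config, path: Path) -> None:
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    payload["config_hash"] = config_hash(config)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def save_report(report: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, set, frozenset)):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
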