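"""Reading and writing the pipeline's on-disk formats.

A plate lives in a directory:

    plate/
      platemap.csv          # well_id,condition,replicate
      truth.json            # optional ground-truth sidecar (simulations)
      wells/
        A01.tif             # one multi-page TIFF per well, or
        A01/frame_000.tif   # a subdirectory of ordered single-frame files

Frames are stored as 16-bit TIFFs; acquisition times are reconstructed
from the configured frame interval (t = 0 at the first frame).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError
from .synthetic import FrameStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_platemap",
    "read_platemap",
    "write_truth",
    "read_truth",
]

PLATEMAP_COLUMNS = ["well_id", "condition", "replicate"]


def write_stack(stack: FrameStack, path: Path) -> Path:
    """Write a stack as one multi-page 16-bit TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.rint(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    return path


def read_stack(source: Path, frame_interval_h: float = 1.0, well_id: str | None = None) -> FrameStack:
    """Read a multi-page TIFF or a directory of ordered single-frame images."""
    source = Path(source)
    if source.is_dir():
        files = sorted(p for p in source.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff", ".png"))
        if not files:
            raise ConfigurationError(f"no image files found in {source}")
        frames = np.stack([tifffile.imread(f) if f.suffix.lower() != ".png"
                           else np.asarray(_read_png(f)) for f in files])
        name = source.name
    elif source.is_file():
        frames = tifffile.imread(source)
        if frames.ndim == 2:
            frames = frames[None]
        name = source.stem
    else:
        raise ConfigurationError(f"image source {source} does not exist")
    times = np.arange(frames.shape[0]) * frame_interval_h
    return FrameStack(well_id=well_id or name, times_h=times, frames=frames.astype(float))


def _read_png(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return iio.imread(path)


def write_platemap(platemap: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    platemap[PLATEMAP_COLUMNS].to_csv(path, index=False)
    return path


def read_platemap(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"plate map {path} does not exist")
    df = pd.read_csv(path)
    missing = [c for c in PLATEMAP_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"plate map {path} lacks columns: {missing}")
    if df["well_id"].duplicated().any():
        raise ConfigurationError("plate map contains duplicate well ids")
    if df["condition"].isna().any() or (df["condition"].astype(str).str.len() == 0).any():
        raise ConfigurationError("every well needs a nonempty condition label")
    return df


def write_truth(truths: dict, path: Path) -> Path:
    """Ground-truth sidecar: well_id -> kinetic + geometry record."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = {wid: gt.to_record() for wid, gt in truths.items()}
    path.write_text(json.dumps(records, indent=2, sort_keys=True))
    return path


def read_truth(path: Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"truth sidecar {path} does not exist")
    return json.loads(path.read_text())
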