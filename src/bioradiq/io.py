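"""Lossless image-stack and table I/O.

Stacks travel as multi-page 16-bit TIFF (or a directory of single-page
TIFFs / whitespace-delimited text matrices); tables are tidy CSV with a
comment header carrying the config hash and seed, and units declared in
every numeric column name.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .quantify import ExposureSchedule, ImageStack

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "read_mask",
    "write_mask",
    "write_table",
    "read_table",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _load_frames(path: Path) -> np.ndarray:
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES | {".txt"}
        )
        if not files:
            raise FileNotFoundError(f"no frame files (*.tif, *.txt) in directory {path}")
        frames = [
            tifffile.imread(f) if f.suffix.lower() in _TIFF_SUFFIXES else np.loadtxt(f)
            for f in files
        ]
        return np.stack(frames)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
        return arr[None] if arr.ndim == 2 else arr
    if path.suffix.lower() == ".txt":
        return np.loadtxt(path)[None]
    raise ValueError(f"unsupported stack format: {path}")


def read_image_stack(path, schedule: ExposureSchedule, pixel_size_um: float = 500.0) -> ImageStack:
    """Load a PSL stack and attach its exposure schedule."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image stack not found: {path}")
    frames = _load_frames(path)
    if frames.shape[0] != len(schedule):
        raise ValueError(
            f"stack {path} has {frames.shape[0]} page(s) but the schedule defines "
            f"{len(schedule)} frame(s)"
        )
    return ImageStack(frames=frames, schedule=schedule, pixel_size_um=pixel_size_um)


def write_image_stack(path, stack: ImageStack) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.uint16), photometric="minisblack")
    return path


def write_mask(path, mask: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))
    return path


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask not found: {path}")
    return tifffile.imread(path)


def write_table(path, df: pd.DataFrame, meta: "Mapping[str, object] | None" = None) -> Path:
    """Write a tidy CSV with '# key=value' provenance comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
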