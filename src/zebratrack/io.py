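"""Frame and table IO: image-sequence directories, video containers, CSV."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_FRAME_SUFFIXES = (".png", ".tif", ".tiff")


class SourceError(IOError):
    """Raised when a frame source cannot be read."""


def _to_gray8(img: np.ndarray) -> np.ndarray:
    """Convert any frame to 8-bit grayscale."""
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def read_frames(source: Union[str, Path]) -> List[np.ndarray]:
    """Load a frame sequence from a numbered PNG/TIFF directory or a video file."""
    path = Path(source)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise SourceError(f"no PNG/TIFF frames found in {path}")
        return [_to_gray8(iio.imread(f)) for f in files]
    if not path.exists():
        raise SourceError(f"frame source {path} does not exist")
    try:
        frames = [_to_gray8(frame) for frame in iio.imiter(path)]
    except Exception as exc:  # plugin missing or unreadable container
        raise SourceError(
            f"cannot read {path} as a video container ({exc}); provide a "
            "directory of numbered PNG/TIFF frames instead") from exc
    if not frames:
        raise SourceError(f"no frames decoded from {path}")
    return frames


def write_frames(frames: np.ndarray, out_dir: Union[str, Path]) -> None:
    """Write frames as zero-padded numbered PNGs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digits = max(len(str(len(frames) - 1)), 4)
    for t, frame in enumerate(frames):
        iio.imwrite(out / f"frame_{t:0{digits}d}.png", frame)


def write_truth(truth: pd.DataFrame, path: Union[str, Path]) -> None:
    truth.to_csv(path, index=False)


def read_truth(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "fish", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise SourceError(f"truth CSV {path} lacks columns {sorted(missing)}")
    return df


def write_trajectories(traj: pd.DataFrame, path: Union[str, Path]) -> None:
    traj.to_csv(path, index=False, float_format="%.3f")


def read_trajectories(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "fish_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise SourceError(f"trajectory CSV {path} lacks columns {sorted(missing)}")
    return df
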