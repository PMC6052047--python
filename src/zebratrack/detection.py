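"""Static background model and per-frame fish segmentation.

The arena is assumed stable, so the background is the per-pixel mean of the
first ``f`` frames.  Foreground pixels are those differing from the background
by more than the grey threshold; 8-connected components above the area
threshold each yield one :class:`Detection` with second-moment (ellipse-fit)
geometry.

Coordinate convention (package-wide): 0-based pixels, x to the right (columns),
y down (rows).  Angles in degrees, measured from the +x axis toward +y; the
raw body tilt ``theta_raw`` is the major-axis direction folded into [-90, 90).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from skimage import measure

from .config import Config


class InputError(ValueError):
    """Raised for malformed image input (empty stacks, shape mismatches)."""


@dataclass
class BackgroundModel:
    """Per-pixel mean of the first f frames plus its global mean grey level."""

    bm: np.ndarray          # float64, frame-shaped
    f: int
    mean_level: float

    @property
    def shape(self) -> Tuple[int, int]:
        return self.bm.shape


@dataclass
class Detection:
    """One segmented fish on one frame."""

    frame_index: int
    centroid: Tuple[float, float]       # (x, y)
    theta_raw: float                    # deg in [-90, 90)
    major: float                        # ellipse-equivalent semi-axes, px
    minor: float
    area: int                           # px^2
    aspect_ratio: float                 # major / minor, >= 1
    mask_id: int                        # component label within the frame
    bbox: Tuple[int, int, int, int]     # (min_row, min_col, max_row, max_col)
    mask: np.ndarray                    # boolean, bbox-shaped

    @property
    def rect(self) -> Tuple[Tuple[float, float], float, float, float]:
        """Oriented enclosing rectangle: (centre, width, height, angle_deg)."""
        return (self.centroid, 2 * self.major, 2 * self.minor, self.theta_raw)


def build_background(frames: Sequence[np.ndarray], f: int) -> BackgroundModel:
    """Average the first ``f`` frames into the static background model.

    Accumulates in float64 so integer frames cannot overflow.
    """
    n = len(frames)
    if n == 0:
        raise InputError("empty frame sequence")
    if not 1 <= f <= n:
        raise InputError(f"f={f} outside [1, {n}]")
    shape = np.asarray(frames[0]).shape
    acc = np.zeros(shape, dtype=np.float64)
    for t in range(f):
        frame = np.asarray(frames[t])
        if frame.shape != shape:
            raise InputError(f"frame {t} has shape {frame.shape}, expected {shape}")
        acc += frame
    bm = acc / f
    return BackgroundModel(bm=bm, f=f, mean_level=float(bm.mean()))


def fit_ellipse(mask: np.ndarray) -> Tuple[Tuple[float, float], float, float, float]:
    """Second-moment-equivalent ellipse of a component mask.

    Returns ``(centre_xy, theta_raw_deg, semi_major, semi_minor)``.
    ``theta_raw`` is 0.5*atan2(2*mu11, mu20-mu02) in degrees, folded to
    [-90, 90); for a degenerate (collinear) component the bounding-box axis is
    used instead, with a warning.
    """
    ys, xs = np.nonzero(mask)
    if xs.size < 5:
        raise InputError(f"component has {xs.size} pixels; need >= 5 for an ellipse fit")
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    mu20 = np.mean(dx * dx)
    mu02 = np.mean(dy * dy)
    mu11 = np.mean(dx * dy)
    det = mu20 * mu02 - mu11 * mu11
    if det <= 1e-12 and min(mu20, mu02) < 1e-12:
        warnings.warn("degenerate component; falling back to bounding-box axis")
        w = xs.max() - xs.min() + 1
        h = ys.max() - ys.min() + 1
        theta = 0.0 if w >= h else -90.0
        return (cx, cy), theta, max(w, h) / 2.0, max(min(w, h) / 2.0, 0.5)
    theta = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    if theta >= 90.0:
        theta -= 180.0
    elif theta < -90.0:
        theta += 180.0
    common = 0.5 * (mu20 + mu02)
    diff = np.sqrt((0.5 * (mu20 - mu02)) ** 2 + mu11 ** 2)
    # 2*sqrt(eigenvalue) equals the true semi-axis for a filled ellipse
    semi_major = 2.0 * np.sqrt(max(common + diff, 1e-12))
    semi_minor = 2.0 * np.sqrt(max(common - diff, 1e-12))
    return (cx, cy), float(theta), float(semi_major), float(semi_minor)


def foreground_mask(frame: np.ndarray, bg: BackgroundModel, cfg: Config) -> np.ndarray:
    """Pixels deviating from the background by more than thr_g.

    Uses the absolute difference so detection works for either polarity; the
    one-sided comparison is reserved for the descriptor's binarization step.
    """
    if frame.shape != bg.shape:
        raise InputError(f"frame shape {frame.shape} != background {bg.shape}")
    return np.abs(frame.astype(np.float64) - bg.bm) > cfg.thr_g


def segment_frame(frame: np.ndarray, bg: BackgroundModel, cfg: Config,
                  frame_index: int = 0) -> List[Detection]:
    """Segment one frame into fish detections.

    Components with area below ``thr_s`` are discarded; survivors are returned
    ordered by component label with ellipse-fit geometry attached.  An empty
    list (e.g. frame equals background) is valid.
    """
    fg = foreground_mask(frame, bg, cfg)
    labels = measure.label(fg, connectivity=2)  # 8-connectivity
    detections: List[Detection] = []
    for prop in measure.regionprops(labels):
        if prop.area < cfg.thr_s:
            continue
        (cx, cy), theta, major, minor = fit_ellipse_from_prop(prop)
        detections.append(Detection(
            frame_index=frame_index,
            centroid=(cx, cy),
            theta_raw=theta,
            major=major,
            minor=minor,
            area=int(prop.area),
            aspect_ratio=major / max(minor, 1e-9),
            mask_id=int(prop.label),
            bbox=tuple(prop.bbox),
            mask=prop.image.copy(),
        ))
    return detections


def fit_ellipse_from_prop(prop) -> Tuple[Tuple[float, float], float, float, float]:
    """fit_ellipse on a regionprops component, in full-frame coordinates."""
    (cx, cy), theta, major, minor = fit_ellipse(prop.image)
    min_row, min_col = prop.bbox[0], prop.bbox[1]
    return (cx + min_col, cy + min_row), theta, major, minor
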