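"""Tracking configuration: segmentation, ROI, descriptor and matching parameters.

All thresholds that the tracker exposes live in a single :class:`Config`
dataclass.  The defaults are the values used throughout the experiments this
package reproduces; in practice only the segmentation pair ``thr_s`` (minimum
blob area) and ``thr_g`` (grey-level contrast) need adjusting between arenas,
which is what the two presets capture.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union


class ConfigError(ValueError):
    """Raised when a configuration value is missing, unknown or out of range."""


@dataclass
class Config:
    """Pipeline parameters.

    Parameters
    ----------
    thr_s : float
        Minimum connected-component area in px² for a blob to count as a fish.
    thr_g : float
        Grey-level threshold on |frame − background| for foreground pixels.
    p_r : int
        Side length in px of the square, rescaled head ROI sample.
    thr_e : float
        Minimum major/minor aspect ratio of the fitted body ellipse; samples
        below it (bent or overlapping bodies) are rejected.
    thr_d : float
        Distance margin in px for rescuing the closer candidate when two
        previous-frame objects share a nearest neighbour (crossing flag off).
    p_c : int
        Minimum foreground-pixel count for a descriptor cell to be marked
        relevant to the back texture.
    p_b : int
        Number of relevant blocks emitted in spiral order; fixes the
        descriptor length at ``p_b * 4 * n_bins``.
    thr_p : float
        Probability below which an accepted tracklet match is flagged for
        manual review, in (0, 1).
    n_bins : int
        Unsigned orientation bins per cell histogram.
    cell_px : int
        Cell side in px (cells do not overlap).
    block_cells : int
        Block side in cells; blocks overlap at one-cell stride.
    f_background : int
        Number of leading frames averaged into the static background model.
    polarity : str
        ``"bright"`` for fish brighter than the background, ``"dark"``
        otherwise; controls the binarization direction.
    head_fraction : float
        Fraction of the rotated body box, measured from the centre toward the
        head, kept as the ROI crop.
    roi_pad : float
        Multiplier on the fitted semi-axes when cutting the body box, so the
        whole body (not just the second-moment ellipse) is covered.
    roi_smooth_sigma : float
        Gaussian smoothing of the resampled ROI patch in output px; removes
        the resampling-grid harmonic that would leak the original body
        orientation into the gradient histograms.  0 disables.
    merge_area_factor : float
        A detection whose area exceeds this multiple of the previous frame's
        median detection area is treated as a merged (overlapping) blob.
    max_match_dist : float
        Maximum centroid displacement in px allowed for a frame-to-frame
        match; guards against cross-arena jumps when a fish is lost.
    cross_window : int
        Frames before a crossing within which ended tracklets join the
        "before" group of the crossing event.
    min_tracklet_len : int
        Tracklets shorter than this many frames are discarded as
        crossing debris.
    svm_c : float
        SVM regularisation parameter.
    svm_gamma : Union[float, str]
        RBF kernel width; ``"auto"`` means 1/n_features.
    seed : int
        Seed for every stochastic step (SVM training shuffles, tie-breaks).
    """

    thr_s: float = 500.0
    thr_g: float = 20.0
    p_r: int = 100
    thr_e: float = 3.0
    thr_d: float = 30.0
    p_c: int = 10
    p_b: int = 34
    thr_p: float = 0.60
    n_bins: int = 9
    cell_px: int = 9
    block_cells: int = 2
    f_background: int = 300
    polarity: str = "bright"
    head_fraction: float = 0.5
    roi_pad: float = 1.2
    roi_smooth_sigma: float = 2.5
    merge_area_factor: float = 1.6
    max_match_dist: float = 100.0
    cross_window: int = 5
    min_tracklet_len: int = 10
    svm_c: float = 10.0
    svm_gamma: Union[float, str] = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "thr_s", "thr_g", "p_r", "thr_e", "thr_d", "p_c", "p_b",
            "n_bins", "cell_px", "block_cells", "f_background",
            "head_fraction", "roi_pad", "max_match_dist", "svm_c",
            "min_tracklet_len", "merge_area_factor",
        ]
        if self.roi_smooth_sigma < 0:
            raise ConfigError("roi_smooth_sigma must be >= 0")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not 0.0 < self.thr_p < 1.0:
            raise ConfigError(f"thr_p must lie in (0, 1), got {self.thr_p!r}")
        if self.polarity not in ("bright", "dark"):
            raise ConfigError(f"polarity must be 'bright' or 'dark', got {self.polarity!r}")
        if not 0.0 < self.head_fraction <= 1.0:
            raise ConfigError(f"head_fraction must lie in (0, 1], got {self.head_fraction!r}")
        if isinstance(self.svm_gamma, str) and self.svm_gamma not in ("auto", "scale"):
            raise ConfigError(f"svm_gamma must be a number, 'auto' or 'scale', got {self.svm_gamma!r}")
        n_cells = self.p_r // self.cell_px
        n_blocks_side = n_cells - (self.block_cells - 1)
        if self.p_b > n_blocks_side ** 2:
            raise ConfigError(
                f"p_b={self.p_b} exceeds the {n_blocks_side}x{n_blocks_side} block grid"
            )

    # -- persistence ------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        """Write the config as flat ``key = value`` lines."""
        lines = []
        for field in dataclasses.fields(self):
            lines.append(f"{field.name} = {getattr(self, field.name)}")
        Path(path).write_text("\n".join(lines) + "\n")


#: Presets for the two arena classes; only the segmentation pair differs.
PRESETS = {
    "small-tank": {"thr_s": 500.0, "thr_g": 20.0},
    "large-tank": {"thr_s": 800.0, "thr_g": 50.0},
}

_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(Config)}
_INT_FIELDS = {
    "p_r", "p_c", "p_b", "n_bins", "cell_px", "block_cells",
    "f_background", "cross_window", "min_tracklet_len", "seed",
}
_STR_FIELDS = {"polarity"}


def _coerce(key: str, raw: str):
    if key in _STR_FIELDS:
        return raw
    if key == "svm_gamma" and raw in ("auto", "scale"):
        return raw
    try:
        if key in _INT_FIELDS:
            return int(raw)
        return float(raw)
    except ValueError as exc:
        raise ConfigError(f"cannot parse {key} = {raw!r}") from exc


def load_config(path: Union[str, Path, None] = None, preset: str | None = None) -> Config:
    """Load a :class:`Config` from a flat key-value file.

    Every key is optional; missing keys take their defaults.  Unknown keys are
    rejected.  Lines starting with ``#`` and blank lines are ignored; keys and
    values are separated by ``=`` or ``:``.
    """
    values: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        values.update(PRESETS[preset])
    if path is not None:
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = "=" if "=" in line else ":"
            if sep not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
            key, raw = (part.strip() for part in line.split(sep, 1))
            if key not in _FIELD_TYPES:
                raise ConfigError(f"line {lineno}: unknown key {key!r}")
            values[key] = _coerce(key, raw)
    return Config(**values)
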