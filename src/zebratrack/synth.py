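"""Synthetic multi-fish videos with ground truth.

Every downstream stage (detection, ROI normalization, texture descriptors,
tracklet building, identity association, metrics) is exercised on videos
produced here, so the generator emulates the features those stages rely on:

* elongated, rigid fish blobs whose anterior (head) half is wider than the
  tail, so the head side carries the larger foreground-pixel sum;
* a per-individual, seeded spot texture painted in body-fixed coordinates on
  the anterior half, rotating rigidly with the heading — a stand-in for the
  individual back-texture "fingerprint" of real fish;
* smooth motion (heading random walk at roughly constant speed, reflective
  arena walls) with an optional attraction term that provokes crossings, in
  which the blobs merge into a single connected component;
* exact per-frame ground truth: centre, heading and a visibility flag that
  drops while a fish overlaps another.

It does not attempt photorealism, body undulation (a rigid parabolic "bend"
flag stands in for deformation) or lighting variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from .config import ConfigError

#: column order of the ground-truth table
TRUTH_COLUMNS = ["frame", "fish", "x", "y", "heading_deg", "visible"]


@dataclass
class SyntheticScene:
    """Parameters of one synthetic recording.

    Angles follow the package-wide image convention: x to the right, y down,
    headings in degrees measured from +x toward +y, range [0, 360).
    """

    n_fish: int = 4
    n_frames: int = 300
    frame_size: Tuple[int, int] = (480, 480)  # (H, W)
    arena_margin: int = 12
    fish_axes: Tuple[float, float] = (28.0, 8.0)  # semi-major, semi-minor px
    texture_seed: int = 0
    speed_mean: float = 3.5
    speed_sd: float = 0.6
    heading_diffusion: float = 0.06  # rad / frame
    background_level: int = 40
    fish_level: int = 170
    crossing_bias: float = 0.0
    bend_amplitude: float = 0.0  # fraction of semi-minor axis
    texture_amp: float = 60.0
    n_spots: int = 12

    def __post_init__(self) -> None:
        h, w = self.frame_size
        a = self.fish_axes[0]
        if self.n_fish < 1 or self.n_frames < 1:
            raise ConfigError("scene needs at least one fish and one frame")
        if self.fish_axes[0] <= self.fish_axes[1]:
            raise ConfigError("fish semi-major axis must exceed the semi-minor axis")
        if min(h, w) <= 2 * (self.arena_margin + a + 2):
            raise ConfigError(
                f"frame_size {self.frame_size} too small for fish of semi-major "
                f"axis {a} inside a {self.arena_margin}px margin"
            )
        if not 0.0 <= self.crossing_bias <= 1.0:
            raise ConfigError("crossing_bias must lie in [0, 1]")
        if not 0 <= self.background_level <= 255 or not 0 <= self.fish_level <= 255:
            raise ConfigError("intensity levels must lie in [0, 255]")


# -- body geometry ---------------------------------------------------------

#: widening of the anterior half relative to the posterior (teardrop shape);
#: gives the head side the larger pixel sum used by head resolution.
_TAPER = 0.35


def _half_width(xb: np.ndarray, a: float, b: float) -> np.ndarray:
    """Half-width of the body outline at body-axis position xb (head at +a)."""
    base = np.sqrt(np.clip(1.0 - (xb / a) ** 2, 0.0, None))
    return b * base * (1.0 + _TAPER * xb / a)


def _make_texture(rng: np.random.Generator, scene: SyntheticScene) -> np.ndarray:
    """Seeded spot field in body coordinates, anterior half only.

    Returned as an image over xb in [-a, a], yb in [-wmax, wmax] at 1 px
    resolution, blurred to a 2-3 px feature scale.
    """
    a, b = scene.fish_axes
    wmax = b * (1.0 + _TAPER)
    nx = int(2 * np.ceil(a)) + 1
    ny = int(2 * np.ceil(wmax)) + 1
    tex = np.zeros((ny, nx))
    for _ in range(scene.n_spots):
        xs = rng.uniform(0.05 * a, 0.92 * a)  # anterior half
        ys = rng.uniform(-0.65 * b, 0.65 * b)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        ix = int(round(xs + a))
        iy = int(round(ys + wmax))
        tex[iy, ix] += sign
    tex = gaussian_filter(tex, sigma=2.2)
    peak = np.abs(tex).max()
    if peak > 0:
        tex *= scene.texture_amp / peak
    return tex


def _sample_texture(tex: np.ndarray, xb: np.ndarray, yb: np.ndarray,
                    a: float, wmax: float) -> np.ndarray:
    """Bilinear sample of the body-frame texture at (xb, yb)."""
    fx = np.clip(xb + a, 0, tex.shape[1] - 1.001)
    fy = np.clip(yb + wmax, 0, tex.shape[0] - 1.001)
    x0 = fx.astype(int)
    y0 = fy.astype(int)
    dx = fx - x0
    dy = fy - y0
    return (tex[y0, x0] * (1 - dx) * (1 - dy)
            + tex[y0, x0 + 1] * dx * (1 - dy)
            + tex[y0 + 1, x0] * (1 - dx) * dy
            + tex[y0 + 1, x0 + 1] * dx * dy)


def _paint_fish(frame: np.ndarray, owner_count: np.ndarray,
                x: float, y: float, heading_rad: float,
                tex: np.ndarray, scene: SyntheticScene) -> np.ndarray:
    """Render one fish into `frame`; returns its boolean mask (frame coords).

    The body edge is feathered over ~1 px (linear coverage ramp), emulating
    optical blur; a hard-aliased outline would inject pose-dependent gradient
    noise no real camera produces.
    """
    a, b = scene.fish_axes
    wmax = b * (1.0 + _TAPER)
    h, w = frame.shape
    r = int(np.ceil(a)) + 2
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    dx = xs - x
    dy = ys - y
    c, s = np.cos(heading_rad), np.sin(heading_rad)
    xb = dx * c + dy * s        # along body axis, head at +a
    yb = -dx * s + dy * c
    if scene.bend_amplitude > 0:
        # parabolic midline offset: lowers the fitted aspect ratio
        yb = yb - scene.bend_amplitude * b * 2.0 * (xb / a) ** 2
    half_w = _half_width(np.clip(xb, -a, a), a, b)
    # approximate signed distance to the outline, positive inside
    d_edge = np.minimum(half_w - np.abs(yb), a - np.abs(xb))
    alpha = np.clip(d_edge + 0.5, 0.0, 1.0)
    touched = alpha > 0
    if not touched.any():
        return np.zeros_like(frame, dtype=bool)
    vals = scene.fish_level + _sample_texture(tex, xb[touched], yb[touched], a, wmax)
    vals = np.clip(vals, 0, 255)
    vals = scene.background_level + alpha[touched] * (vals - scene.background_level)
    sub = frame[y0:y1, x0:x1]
    sub[touched] = np.maximum(sub[touched], vals)
    # overlap bookkeeping uses the 1-px-dilated support: segmentation merges
    # 8-connected components, so even a one-pixel gap joins two blobs
    support = binary_dilation(touched)
    owner_count[y0:y1, x0:x1][support] += 1
    mask = np.zeros_like(frame, dtype=bool)
    mask[y0:y1, x0:x1] = support
    return mask


# -- motion ----------------------------------------------------------------

def _wrap_angle(rad: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - rad, 2 * np.pi)


def _simulate_motion(scene: SyntheticScene, rng: np.random.Generator
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Return positions (T, n, 2) and headings (T, n) in radians."""
    h, w = scene.frame_size
    a = scene.fish_axes[0]
    lo = scene.arena_margin + a
    hi_x, hi_y = w - 1 - lo, h - 1 - lo
    n = scene.n_fish
    pos = np.empty((scene.n_frames, n, 2))
    head = np.empty((scene.n_frames, n))
    # spread the fish out initially so tracklets start clean
    pos[0, :, 0] = rng.uniform(lo, hi_x, size=n)
    pos[0, :, 1] = rng.uniform(lo, hi_y, size=n)
    for _ in range(20):  # push apart initial overlaps
        moved = False
        for i in range(n):
            for j in range(i + 1, n):
                d = pos[0, j] - pos[0, i]
                dist = np.hypot(*d)
                if dist < 2.5 * a:
                    shift = (d / max(dist, 1e-6)) * (2.5 * a - dist) / 2
                    pos[0, i] = np.clip(pos[0, i] - shift, lo, [hi_x, hi_y])
                    pos[0, j] = np.clip(pos[0, j] + shift, lo, [hi_x, hi_y])
                    moved = True
        if not moved:
            break
    head[0] = rng.uniform(0, 2 * np.pi, size=n)
    for t in range(1, scene.n_frames):
        turn = rng.normal(0.0, scene.heading_diffusion, size=n)
        if scene.crossing_bias > 0 and n > 1:
            # attraction toward the nearest conspecific, released at close
            # range so that encounters are transient fly-throughs (crossings)
            # rather than permanent clumps
            a = scene.fish_axes[0]
            for i in range(n):
                d = pos[t - 1] - pos[t - 1, i]
                dist = np.hypot(d[:, 0], d[:, 1])
                dist[i] = np.inf
                j = int(np.argmin(dist))
                if dist[j] > 3.0 * a:
                    desired = np.arctan2(d[j, 1], d[j, 0])
                    turn[i] += scene.crossing_bias * 0.35 * _wrap_angle(desired - head[t - 1, i])
        head[t] = head[t - 1] + turn
        speed = np.clip(rng.normal(scene.speed_mean, scene.speed_sd, size=n), 0.0, None)
        step = np.stack([np.cos(head[t]), np.sin(head[t])], axis=1) * speed[:, None]
        pos[t] = pos[t - 1] + step
        # reflective walls
        for k, (lo_k, hi_k) in enumerate([(lo, hi_x), (lo, hi_y)]):
            under = pos[t, :, k] < lo_k
            over = pos[t, :, k] > hi_k
            pos[t, under, k] = 2 * lo_k - pos[t, under, k]
            pos[t, over, k] = 2 * hi_k - pos[t, over, k]
            flip = under | over
            if flip.any():
                if k == 0:
                    head[t, flip] = np.pi - head[t, flip]
                else:
                    head[t, flip] = -head[t, flip]
        head[t] = np.mod(head[t], 2 * np.pi)
    return pos, head


# -- public API ------------------------------------------------------------

def make_textures(scene: SyntheticScene) -> list:
    """Per-fish body-frame texture fields (deterministic in texture_seed)."""
    rng = np.random.default_rng(scene.texture_seed)
    return [_make_texture(rng, scene) for _ in range(scene.n_fish)]


def generate_video(scene: SyntheticScene) -> Tuple[np.ndarray, pd.DataFrame]:
    """Render the scene.

    Returns
    -------
    frames : uint8 array of shape (n_frames, H, W)
    truth : DataFrame with one row per (frame, fish):
        frame, fish, x, y, heading_deg, visible.  ``visible`` is False on
        frames where the fish's pixels intersect another fish's pixels.
    """
    rng = np.random.default_rng(scene.texture_seed)
    textures = [_make_texture(rng, scene) for _ in range(scene.n_fish)]
    pos, head = _simulate_motion(scene, rng)
    h, w = scene.frame_size
    frames = np.empty((scene.n_frames, h, w), dtype=np.uint8)
    records = []
    for t in range(scene.n_frames):
        frame = np.full((h, w), float(scene.background_level))
        owners = np.zeros((h, w), dtype=np.uint8)
        masks = []
        for i in range(scene.n_fish):
            masks.append(_paint_fish(frame, owners, pos[t, i, 0], pos[t, i, 1],
                                     head[t, i], textures[i], scene))
        frames[t] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        # the recorded centre is the blob's area centroid: the teardrop body
        # is head-heavy, shifting the pixel centroid TAPER*a/4 toward the head
        centroid_off = _TAPER * scene.fish_axes[0] / 4.0
        for i in range(scene.n_fish):
            overlapped = bool((owners[masks[i]] > 1).any())
            records.append((t, i,
                            pos[t, i, 0] + centroid_off * np.cos(head[t, i]),
                            pos[t, i, 1] + centroid_off * np.sin(head[t, i]),
                            float(np.degrees(head[t, i]) % 360.0), not overlapped))
    truth = pd.DataFrame.from_records(records, columns=TRUTH_COLUMNS)
    return frames, truth


def render_posed(scene: SyntheticScene, fish: int,
                 headings_deg: Sequence[float],
                 centre: Optional[Tuple[float, float]] = None
                 ) -> np.ndarray:
    """Render one fish at the frame centre at a list of fixed headings.

    One frame per heading; used to probe orientation robustness of the
    descriptors with exact pose control.
    """
    if not 0 <= fish < scene.n_fish:
        raise ConfigError(f"fish index {fish} out of range for n_fish={scene.n_fish}")
    textures = make_textures(scene)
    h, w = scene.frame_size
    if centre is None:
        centre = ((w - 1) / 2.0, (h - 1) / 2.0)
    frames = np.empty((len(headings_deg), h, w), dtype=np.uint8)
    for t, hd in enumerate(headings_deg):
        frame = np.full((h, w), float(scene.background_level))
        owners = np.zeros((h, w), dtype=np.uint8)
        _paint_fish(frame, owners, centre[0], centre[1],
                    np.radians(hd), textures[fish], scene)
        frames[t] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    return frames


def background_frame(scene: SyntheticScene) -> np.ndarray:
    """A fish-free frame at the scene's background level (for background models)."""
    h, w = scene.frame_size
    return np.full((h, w), scene.background_level, dtype=np.uint8)
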