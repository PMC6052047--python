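"""Relevance-masked, spiral-ordered HOG back-texture descriptor.

Standard histogram-of-oriented-gradients machinery — non-overlapping cells,
2×2-cell blocks at one-cell stride, L2 block normalization — with two
additions that make the descriptor a stable individual fingerprint:

* cells whose binarized-body foreground count falls below ``p_c`` are marked
  irrelevant, and a block is kept only if at least one member cell is
  relevant, so background blocks never enter the feature;
* the relevant blocks are emitted in a fixed outward spiral from the grid
  centre and truncated/zero-padded to exactly ``p_b`` blocks, giving every
  sample the same length regardless of body pose.

Applied to head-right-normalized ROI patches this yields a low-dimensional,
orientation-robust descriptor; applied to raw crops (see
:func:`plain_hog`) it reproduces the orientation-sensitive baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .config import Config
from .detection import BackgroundModel, InputError
from .roi import FishROI

_EPS = 1e-10


@dataclass
class HOGMap:
    """Per-cell orientation histograms and normalized block descriptors."""

    cell_hist: np.ndarray    # (cells_y, cells_x, n_bins)
    blocks: np.ndarray       # (cells_y-1, cells_x-1, 4*n_bins), L2-normalized
    n_bins: int


@dataclass
class RelevanceMask:
    """Binary masks marking texture-bearing cells and blocks."""

    cell_mask: np.ndarray    # bool (cells_y, cells_x)
    block_mask: np.ndarray   # bool (cells_y-1, cells_x-1)


@dataclass
class HOGFeature:
    """Fixed-length spiral descriptor: p_b blocks of 4*n_bins values each."""

    vector: np.ndarray
    n_blocks_found: int
    padded: bool
    coords: List[Tuple[int, int]]    # (row, col) of each selected block


def binarize(patch: np.ndarray, mean_level: float, polarity: str = "bright") -> np.ndarray:
    """Foreground map of a sample patch against the background mean grey level.

    A pixel is foreground when strictly brighter than the background average
    (strictly darker for ``polarity='dark'``).
    """
    if polarity == "bright":
        return patch > mean_level
    return patch < mean_level


def _gradients(patch: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Centered [-1, 0, 1] differences; border gradients are zero."""
    p = patch.astype(np.float64)
    gx = np.zeros_like(p)
    gy = np.zeros_like(p)
    gx[:, 1:-1] = p[:, 2:] - p[:, :-2]
    gy[1:-1, :] = p[2:, :] - p[:-2, :]
    return gx, gy


def hog_map(patch: np.ndarray, cfg: Config) -> HOGMap:
    """Cell histograms and block-normalized descriptors of one patch.

    Unsigned orientations (0–180°) are binned by containing interval with
    magnitude-weighted votes; no interpolation across bins or cells.  Cells
    are ``cell_px`` square and do not overlap; any remainder rows/columns at
    the right/bottom edge are ignored.  Blocks are ``block_cells`` square at
    one-cell stride and L2-normalized.
    """
    h, w = patch.shape
    cell = cfg.cell_px
    cells_y, cells_x = h // cell, w // cell
    if cells_y < cfg.block_cells or cells_x < cfg.block_cells:
        raise InputError(
            f"patch {patch.shape} smaller than one {cfg.block_cells}x{cfg.block_cells}-cell block")
    gx, gy = _gradients(patch)
    crop_y, crop_x = cells_y * cell, cells_x * cell
    gx = gx[:crop_y, :crop_x]
    gy = gy[:crop_y, :crop_x]
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0
    bins = np.minimum((ang / (180.0 / cfg.n_bins)).astype(int), cfg.n_bins - 1)

    rows = np.arange(crop_y) // cell
    cols = np.arange(crop_x) // cell
    cell_idx = rows[:, None] * cells_x + cols[None, :]
    flat_idx = cell_idx * cfg.n_bins + bins
    hist = np.bincount(flat_idx.ravel(), weights=mag.ravel(),
                       minlength=cells_y * cells_x * cfg.n_bins)
    cell_hist = hist.reshape(cells_y, cells_x, cfg.n_bins)

    b = cfg.block_cells
    by, bx = cells_y - b + 1, cells_x - b + 1
    blocks = np.empty((by, bx, b * b * cfg.n_bins))
    for i in range(by):
        for j in range(bx):
            v = cell_hist[i:i + b, j:j + b].ravel()
            blocks[i, j] = v / np.sqrt(np.dot(v, v) + _EPS ** 2)
    return HOGMap(cell_hist=cell_hist, blocks=blocks, n_bins=cfg.n_bins)


def relevance_mask(binary_patch: np.ndarray, cfg: Config) -> RelevanceMask:
    """Mark texture-bearing cells (>= p_c foreground pixels) and their blocks."""
    h, w = binary_patch.shape
    cell = cfg.cell_px
    cells_y, cells_x = h // cell, w // cell
    crop = binary_patch[:cells_y * cell, :cells_x * cell].astype(np.int64)
    counts = crop.reshape(cells_y, cell, cells_x, cell).sum(axis=(1, 3))
    cell_mask = counts >= cfg.p_c
    b = cfg.block_cells
    by, bx = cells_y - b + 1, cells_x - b + 1
    block_mask = np.zeros((by, bx), dtype=bool)
    for i in range(by):
        for j in range(bx):
            block_mask[i, j] = cell_mask[i:i + b, j:j + b].any()
    return RelevanceMask(cell_mask=cell_mask, block_mask=block_mask)


def spiral_coords(rows: int, cols: int) -> List[Tuple[int, int]]:
    """Grid positions in outward spiral order from the centre.

    Starts at the grid centre (for even side lengths: the upper-left element
    of the central 2×2), first step to the right, turning clockwise on the
    image grid (right, down, left, up).  Off-grid positions of the widening
    walk are skipped; every position appears exactly once.
    """
    r = (rows - 1) // 2
    c = (cols - 1) // 2
    out = [(r, c)]
    steps = [(0, 1), (1, 0), (0, -1), (-1, 0)]  # right, down, left, up
    run, leg = 1, 0
    while len(out) < rows * cols:
        dr, dc = steps[leg % 4]
        for _ in range(run):
            r += dr
            c += dc
            if 0 <= r < rows and 0 <= c < cols:
                out.append((r, c))
        leg += 1
        if leg % 2 == 0:
            run += 1
    return out


def spiral_select(hmap: HOGMap, mask: RelevanceMask, p_b: int) -> HOGFeature:
    """Concatenate the first ``p_b`` relevant blocks in spiral order.

    Zero-pads (and flags) when fewer than ``p_b`` relevant blocks exist, so
    the descriptor length is always ``p_b * block_cells^2 * n_bins``.
    """
    by, bx, blen = hmap.blocks.shape
    if mask.block_mask.shape != (by, bx):
        raise InputError(
            f"mask shape {mask.block_mask.shape} != block grid {(by, bx)}")
    coords: List[Tuple[int, int]] = []
    for (r, c) in spiral_coords(by, bx):
        if mask.block_mask[r, c]:
            coords.append((r, c))
            if len(coords) == p_b:
                break
    vec = np.zeros(p_b * blen)
    for k, (r, c) in enumerate(coords):
        vec[k * blen:(k + 1) * blen] = hmap.blocks[r, c]
    return HOGFeature(vector=vec, n_blocks_found=len(coords),
                      padded=len(coords) < p_b, coords=coords)


def extract_feature(roi: FishROI, bg: BackgroundModel, cfg: Config) -> HOGFeature:
    """Full descriptor of one accepted ROI: binarize → HOG → mask → spiral."""
    if not roi.accepted:
        raise InputError(f"ROI quality is {roi.quality!r}; only accepted ROIs "
                         "may enter feature extraction")
    binary = binarize(roi.patch, bg.mean_level, cfg.polarity)
    hmap = hog_map(roi.patch, cfg)
    mask = relevance_mask(binary, cfg)
    return spiral_select(hmap, mask, cfg.p_b)


def plain_hog(patch: np.ndarray, cfg: Config) -> np.ndarray:
    """Orientation-sensitive baseline: all blocks, row-major, no masking."""
    return hog_map(patch, cfg).blocks.ravel().copy()


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))
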