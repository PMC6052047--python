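import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zebratrack import Config
from zebratrack.detection import InputError
from zebratrack.hog import (binarize, cosine_similarity, extract_feature,
                            hog_map, plain_hog, relevance_mask, spiral_coords,
                            spiral_select)


# -- binarization ----------------------------------------------------------

def test_binarize_boundary_is_strict():
    patch = np.full((10, 10), 50.0)
    assert not binarize(patch, 50.0).any()          # equal -> background
    assert binarize(patch + 1.0, 50.0).all()


def test_binarize_matches_pixel_loop(cfg):
    rng = np.random.default_rng(0)
    patch = rng.integers(0, 256, size=(20, 20)).astype(float)
    out = binarize(patch, 127.0)
    for y in range(20):
        for x in range(20):
            assert out[y, x] == (patch[y, x] > 127.0)


def test_binarize_dark_polarity():
    patch = np.full((5, 5), 10.0)
    assert binarize(patch, 50.0, polarity="dark").all()


# -- HOG map ---------------------------------------------------------------

def test_constant_patch_has_zero_histograms(cfg):
    hmap = hog_map(np.full((100, 100), 37.0), cfg)
    assert not hmap.cell_hist.any()
    assert hmap.cell_hist.shape == (11, 11, 9)
    assert hmap.blocks.shape == (10, 10, 36)


def test_vertical_step_edge_votes_horizontal_gradient_bin(cfg):
    """A vertical edge has a pure x gradient: all mass in the first bin."""
    patch = np.zeros((100, 100))
    patch[:, 50:] = 200.0
    hmap = hog_map(patch, cfg)
    hist = hmap.cell_hist.sum(axis=(0, 1))
    assert hist[0] > 0
    assert hist[1:].sum() == 0


def test_cell_histograms_match_naive_accumulation(cfg):
    rng = np.random.default_rng(5)
    patch = rng.uniform(0, 255, size=(100, 100))
    hmap = hog_map(patch, cfg)
    # independent per-pixel loop
    cell = cfg.cell_px
    oracle = np.zeros((11, 11, cfg.n_bins))
    for y in range(99):
        for x in range(99):
            gx = patch[y, x + 1] - patch[y, x - 1] if 1 <= x <= 98 else 0.0
            gy = patch[y + 1, x] - patch[y - 1, x] if 1 <= y <= 98 else 0.0
            mag = np.hypot(gx, gy)
            ang = np.degrees(np.arctan2(gy, gx)) % 180.0
            b = min(int(ang // 20.0), cfg.n_bins - 1)
            oracle[y // cell, x // cell, b] += mag
    np.testing.assert_allclose(hmap.cell_hist, oracle, atol=1e-6)


def test_block_norms_bounded(cfg):
    rng = np.random.default_rng(9)
    hmap = hog_map(rng.uniform(0, 255, size=(100, 100)), cfg)
    norms = np.linalg.norm(hmap.blocks, axis=-1)
    assert (norms <= 1.0 + 1e-9).all()


def test_patch_smaller_than_block_rejected(cfg):
    with pytest.raises(InputError):
        hog_map(np.zeros((12, 12)), cfg)


# -- relevance masking -----------------------------------------------------

def test_empty_binary_patch_masks_everything_off(cfg):
    mask = relevance_mask(np.zeros((100, 100), dtype=bool), cfg)
    assert not mask.cell_mask.any()
    assert not mask.block_mask.any()


def test_cell_with_exactly_threshold_pixels_is_relevant(cfg):
    binary = np.zeros((100, 100), dtype=bool)
    cell_y, cell_x = 4, 6
    ys, xs = np.unravel_index(np.arange(cfg.p_c), (9, 9))
    binary[cell_y * 9 + ys, cell_x * 9 + xs] = True
    mask = relevance_mask(binary, cfg)
    assert mask.cell_mask.sum() == 1
    assert mask.cell_mask[cell_y, cell_x]
    covering = mask.block_mask.nonzero()
    assert 1 <= len(covering[0]) <= 4
    for by, bx in zip(*covering):
        assert by <= cell_y <= by + 1 and bx <= cell_x <= bx + 1
    # one pixel fewer -> irrelevant
    binary[cell_y * 9 + ys[0], cell_x * 9 + xs[0]] = False
    assert not relevance_mask(binary, cfg).cell_mask.any()


def test_relevance_mask_matches_counting_oracle(cfg):
    rng = np.random.default_rng(3)
    binary = rng.random((100, 100)) < 0.12
    mask = relevance_mask(binary, cfg)
    for cy in range(11):
        for cx in range(11):
            count = binary[cy * 9:(cy + 1) * 9, cx * 9:(cx + 1) * 9].sum()
            assert mask.cell_mask[cy, cx] == (count >= cfg.p_c)
    for by in range(10):
        for bx in range(10):
            assert mask.block_mask[by, bx] == mask.cell_mask[by:by + 2, bx:bx + 2].any()


def test_uniform_offset_below_margin_keeps_mask(cfg):
    """Background shifts smaller than the fg/bg margin leave the mask alone."""
    rng = np.random.default_rng(7)
    patch = np.full((100, 100), 40.0)
    patch[30:60, 20:80] = 170.0 + rng.uniform(-20, 20, size=(30, 60))
    mean_level = 55.0      # arena-mean grey sits above the local background
    base = relevance_mask(binarize(patch, mean_level), cfg)
    shifted = relevance_mask(binarize(patch + 10.0, mean_level), cfg)
    assert np.array_equal(base.cell_mask, shifted.cell_mask)
    assert np.array_equal(base.block_mask, shifted.block_mask)


# -- spiral ordering -------------------------------------------------------

def _ring_walk_oracle(rows, cols):
    """Closed-form ring enumerator: centre, then clockwise rings entered at
    the top of the right edge (first step of the walk is to the right)."""
    sr, sc = (rows - 1) // 2, (cols - 1) // 2
    coords = [(sr, sc)]
    k = 1
    while len(coords) < rows * cols:
        ring = ([(r, k) for r in range(1 - k, k + 1)]          # right edge, down
                + [(k, c) for c in range(k - 1, -k - 1, -1)]   # bottom, leftward
                + [(r, -k) for r in range(k - 1, -k - 1, -1)]  # left edge, up
                + [(-k, c) for c in range(1 - k, k + 1)])      # top, rightward
        for dr, dc in ring:
            r, c = sr + dr, sc + dc
            if 0 <= r < rows and 0 <= c < cols:
                coords.append((r, c))
        k += 1
    return coords


@pytest.mark.parametrize("rows,cols", [(1, 1), (3, 3), (4, 4), (10, 10),
                                       (5, 8), (2, 7)])
def test_spiral_matches_ring_walk_oracle(rows, cols):
    assert spiral_coords(rows, cols) == _ring_walk_oracle(rows, cols)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(rows=st.integers(1, 12), cols=st.integers(1, 12))
def test_spiral_is_a_permutation_of_the_grid(rows, cols):
    coords = spiral_coords(rows, cols)
    assert len(coords) == rows * cols
    assert len(set(coords)) == rows * cols
    assert coords[0] == ((rows - 1) // 2, (cols - 1) // 2)


# -- spiral selection ------------------------------------------------------

def test_all_relevant_blocks_give_full_unpadded_vector(cfg):
    rng = np.random.default_rng(1)
    hmap = hog_map(rng.uniform(0, 255, (100, 100)), cfg)
    mask = relevance_mask(np.ones((100, 100), dtype=bool), cfg)
    feat = spiral_select(hmap, mask, cfg.p_b)
    assert feat.vector.shape == (34 * 4 * 9,)
    assert feat.n_blocks_found == 34
    assert not feat.padded
    assert feat.coords == spiral_coords(10, 10)[:34]


def test_no_relevant_blocks_give_zero_padded_vector(cfg):
    rng = np.random.default_rng(1)
    hmap = hog_map(rng.uniform(0, 255, (100, 100)), cfg)
    mask = relevance_mask(np.zeros((100, 100), dtype=bool), cfg)
    feat = spiral_select(hmap, mask, cfg.p_b)
    assert not feat.vector.any()
    assert feat.n_blocks_found == 0
    assert feat.padded


def test_selected_blocks_follow_spiral_order_on_random_mask(cfg):
    rng = np.random.default_rng(12)
    hmap = hog_map(rng.uniform(0, 255, (100, 100)), cfg)
    binary = rng.random((100, 100)) < 0.1
    mask = relevance_mask(binary, cfg)
    feat = spiral_select(hmap, mask, cfg.p_b)
    oracle = [rc for rc in _ring_walk_oracle(10, 10)
              if mask.block_mask[rc]][:cfg.p_b]
    assert feat.coords == oracle
    for k, (r, c) in enumerate(feat.coords):
        np.testing.assert_array_equal(feat.vector[k * 36:(k + 1) * 36],
                                      hmap.blocks[r, c])


# -- end-to-end descriptor -------------------------------------------------

def test_identical_rois_give_identical_features(scene5, bg5, cfg):
    from zebratrack import extract_roi, full_angle, resolve_head, segment_frame
    from zebratrack.synth import render_posed

    frame = render_posed(scene5, 0, [45.0])[0]
    det = segment_frame(frame, bg5, cfg)[0]
    theta = full_angle(det.theta_raw, resolve_head(frame, det))
    roi = extract_roi(frame, det, theta, cfg, bg5)
    a = extract_feature(roi, bg5, cfg)
    b = extract_feature(roi, bg5, cfg)
    np.testing.assert_array_equal(a.vector, b.vector)


def test_rejected_roi_refused(scene5, bg5, cfg):
    from zebratrack.roi import FishROI
    roi = FishROI(np.zeros((100, 100), np.float32), 0, 0, 0.0, "rejected_aspect")
    with pytest.raises(InputError):
        extract_feature(roi, bg5, cfg)


def test_same_fish_two_headings_more_similar_than_two_fish(posed_features):
    """Pose-normalized features: 0 vs 137 deg of one fish beats cross-fish."""
    features, _ = posed_features
    idx_0, idx_137 = 0, 19        # headings 0 and 136.8 deg of the 50-step sweep
    same = cosine_similarity(features[0][idx_0], features[0][idx_137])
    cross = cosine_similarity(features[0][idx_0], features[1][idx_0])
    assert same >= 0.9
    assert cross < same


def test_feature_length_constant_across_poses(posed_features, cfg):
    features, _ = posed_features
    expected = cfg.p_b * 4 * cfg.n_bins
    for f in features:
        assert f.shape[1] == expected
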