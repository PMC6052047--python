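"""Shared fixtures: configs, scenes and cached posed renders."""

from __future__ import annotations

import numpy as np
import pytest

from zebratrack import Config, SyntheticScene, build_background
from zebratrack.synth import background_frame


@pytest.fixture
def cfg() -> Config:
    return Config()


@pytest.fixture(scope="session")
def scene5() -> SyntheticScene:
    """Five textured fish; used for posed (fixed-heading) renders."""
    return SyntheticScene(n_fish=5, n_frames=1, texture_seed=3)


@pytest.fixture(scope="session")
def bg5(scene5):
    """Background model of the empty arena of scene5."""
    return build_background([background_frame(scene5)], 1)


@pytest.fixture(scope="session")
def posed_features(scene5, bg5):
    """Spiral-HOG features of each of the 5 fish at 50 fixed headings.

    Returns (features, plain) where features[f] is a (50, dim) array of the
    orientation-normalized descriptors of fish f and plain[f] the matching
    orientation-sensitive baseline (raw axis-aligned crop, all blocks).
    """
    from skimage.transform import resize

    from zebratrack import extract_feature, extract_roi, full_angle, plain_hog, resolve_head, segment_frame
    from zebratrack.synth import render_posed

    cfg = Config()
    headings = np.linspace(0.0, 360.0, 50, endpoint=False)
    features, plain = [], []
    for fish in range(scene5.n_fish):
        frames = render_posed(scene5, fish, headings)
        fs, ps = [], []
        for frame in frames:
            det = segment_frame(frame, bg5, cfg)[0]
            theta = full_angle(det.theta_raw, resolve_head(frame, det))
            roi = extract_roi(frame, det, theta, cfg, bg5)
            fs.append(extract_feature(roi, bg5, cfg).vector)
            r0, c0, r1, c1 = det.bbox
            crop = frame[r0:r1, c0:c1].astype(float)
            side = max(crop.shape)
            square = np.full((side, side), bg5.mean_level)
            square[:crop.shape[0], :crop.shape[1]] = crop
            patch = resize(square, (cfg.p_r, cfg.p_r), order=1,
                           preserve_range=True)
            ps.append(plain_hog(patch, cfg))
        features.append(np.vstack(fs))
        plain.append(np.vstack(ps))
    return features, plain
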