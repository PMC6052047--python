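"""Identify the individual missing from a group by its unmatched class label.

The procedure used to single out a treated fish in a shoal: train a
classifier on N individuals, classify the M < N individuals of a second
recording, assign test identities to training classes one-to-one, and read
off the training class that received no match — the absent (treated) fish.

Here: train on 4 rendered fish, test on 3 of them; fish 2 is withheld.
"""

import numpy as np

from zebratrack import (Config, SyntheticScene, build_background, extract_feature,
                        extract_roi, full_angle, resolve_head, segment_frame)
from zebratrack.identity import classify_tracklet, match_groups, train_group_classifier
from zebratrack.synth import background_frame, render_posed

cfg = Config()
scene = SyntheticScene(n_fish=4, n_frames=1, texture_seed=9)
bg = build_background([background_frame(scene)], 1)
rng = np.random.default_rng(0)


def features_of(fish, headings):
    out = []
    for frame in render_posed(scene, fish, headings):
        det = segment_frame(frame, bg, cfg)[0]
        theta = full_angle(det.theta_raw, resolve_head(frame, det))
        roi = extract_roi(frame, det, theta, cfg, bg)
        out.append(extract_feature(roi, bg, cfg).vector)
    return np.vstack(out)


train = {fish: features_of(fish, rng.uniform(0, 360, 25)) for fish in range(4)}
clf = train_group_classifier(train, cfg)

withheld = 2
present = [f for f in range(4) if f != withheld]
rows = [classify_tracklet(clf, features_of(f, rng.uniform(0, 360, 10)))
        for f in present]
p = np.vstack(rows)

assign = match_groups(p, n=4, thr_p=cfg.thr_p)
print("probability matrix (rows = test fish, cols = training classes):")
print(np.round(p, 3))
print("assignment:", {f"test{f}": f"class{c}" for f, c in zip(present, assign.labels)})
print("unmatched class:", assign.unmatched_classes)
print()
print(f"The class left without a match is {assign.unmatched_classes[0]} — "
      f"the withheld fish was {withheld}.")
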