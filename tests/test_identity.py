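import itertools

import numpy as np
import pytest

from zebratrack import Config
from zebratrack.identity import (IdentityError, _best_reference_group,
                                 classify_tracklet, final_trajectories,
                                 match_groups, select_training_group,
                                 stitch_and_accumulate, train_group_classifier)
from zebratrack.tracklets import CrossingEvent, Tracklet


# -- training-group selection ----------------------------------------------

def test_longer_shortest_member_trains():
    assert select_training_group([120, 150, 130], [40, 200, 90]) == 0
    assert select_training_group([40, 200], [120, 130]) == 1


def test_tie_goes_to_the_earlier_group():
    assert select_training_group([50, 80], [50, 200]) == 0


def test_group_selection_matches_min_compare_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = rng.integers(10, 300, size=rng.integers(1, 6)).tolist()
        b = rng.integers(10, 300, size=rng.integers(1, 6)).tolist()
        got = select_training_group(a, b)
        assert got == (0 if min(a) >= min(b) else 1)


def test_empty_group_rejected():
    with pytest.raises(IdentityError):
        select_training_group([], [10])


# -- classifier training and per-tracklet probabilities --------------------

def test_classifier_separates_fixture_fish(posed_features, cfg):
    """Two fish, 50 pose-normalized samples each: resubstitution >= 95%."""
    features, _ = posed_features
    clf = train_group_classifier({0: features[0], 1: features[1]}, cfg)
    for label in (0, 1):
        pred = clf.predict(features[label])
        assert np.mean(pred == label) >= 0.95
    row = classify_tracklet(clf, features[0])
    assert int(np.argmax(row)) == list(clf.classes_).index(0)


def test_identical_classes_are_near_indifferent_and_rejected(cfg):
    """Indistinguishable classes: probabilities hover near 0.5, and matching
    two equally ambiguous tracklets fails the 1/N acceptance rule."""
    rng = np.random.default_rng(4)
    shared = rng.normal(size=(30, 20))
    clf = train_group_classifier({0: shared, 1: shared.copy()}, cfg)
    row = classify_tracklet(clf, shared)
    assert row == pytest.approx([0.5, 0.5], abs=0.15)
    p = np.vstack([row, row])   # two equally ambiguous test tracklets
    assert not match_groups(p, n=2, thr_p=cfg.thr_p).accepted


def test_single_class_group_rejected(cfg):
    with pytest.raises(IdentityError):
        train_group_classifier({0: np.ones((5, 4))}, cfg)


def test_member_without_samples_rejected(cfg):
    with pytest.raises(IdentityError):
        train_group_classifier({0: np.ones((5, 4)), 1: np.empty((0, 4))}, cfg)


def test_tracklet_probability_is_frame_mean():
    class StubClassifier:
        classes_ = np.array([0, 1, 2])
        def predict_proba(self, feats):
            return np.array([[0.8, 0.1, 0.1],
                             [0.2, 0.6, 0.2],
                             [0.5, 0.2, 0.3]])
    row = classify_tracklet(StubClassifier(), np.zeros((3, 2)))
    np.testing.assert_allclose(row, [0.5, 0.3, 0.2])


def test_empty_tracklet_yields_uniform_row():
    class StubClassifier:
        classes_ = np.array([0, 1])
        def predict_proba(self, feats):  # pragma: no cover
            raise AssertionError
    row = classify_tracklet(StubClassifier(), np.empty((0, 2)))
    np.testing.assert_allclose(row, [0.5, 0.5])


# -- group matching --------------------------------------------------------

def test_identity_matrix_matches_diagonally():
    assign = match_groups(np.eye(3), n=3, thr_p=0.6)
    assert assign.labels == [0, 1, 2]
    assert assign.accepted
    assert assign.unmatched_classes == []


def test_probability_exactly_one_over_n_is_rejected():
    p = np.array([[0.5, 0.5], [0.9, 0.1]])
    assign = match_groups(p, n=2, thr_p=0.6)
    assert not assign.accepted          # the strict > 1/N rule


def test_low_confidence_match_flagged():
    p = np.array([[0.55, 0.45], [0.1, 0.9]])
    assign = match_groups(p, n=2, thr_p=0.6)
    assert assign.accepted              # both above 1/2
    assert assign.flagged_low_confidence == [0]


def test_rectangular_matrix_reports_unmatched_classes():
    p = np.array([[0.7, 0.1, 0.2],
                  [0.1, 0.2, 0.7]])
    assign = match_groups(p, n=3, thr_p=0.6)
    assert assign.labels == [0, 2]
    assert assign.unmatched_classes == [1]


def test_more_rows_than_columns_rejected():
    with pytest.raises(IdentityError):
        match_groups(np.ones((3, 2)) / 2, n=2, thr_p=0.6)
    with pytest.raises(IdentityError):
        match_groups(np.empty((0, 0)), n=1, thr_p=0.6)


def test_match_groups_equals_permutation_enumeration():
    rng = np.random.default_rng(77)
    for _ in range(100):
        n = int(rng.integers(2, 5))
        p = rng.random((n, n))
        assign = match_groups(p, n=n, thr_p=0.6)
        best = max(itertools.permutations(range(n)),
                   key=lambda perm: sum(p[i, perm[i]] for i in range(n)))
        assert assign.score == pytest.approx(sum(p[i, best[i]] for i in range(n)))
        assert assign.labels == list(best)


def test_no_class_assigned_twice():
    rng = np.random.default_rng(5)
    for _ in range(20):
        rows = int(rng.integers(2, 5))
        cols = int(rng.integers(rows, 7))
        assign = match_groups(rng.random((rows, cols)), n=cols, thr_p=0.6)
        taken = [c for c in assign.labels if c is not None]
        assert len(taken) == len(set(taken))


# -- stitching -------------------------------------------------------------

def _cluster_features(rng, centre, n=30, dim=24):
    return centre + 0.05 * rng.normal(size=(n, dim))


def _make_tracklet(tid, start, length):
    return Tracklet(id=tid, entries=[(start + k, 0) for k in range(length)])


def test_one_crossing_stitches_into_two_tracklets(cfg):
    rng = np.random.default_rng(8)
    ca = np.zeros(24); ca[0] = 1.0
    cb = np.zeros(24); cb[1] = 1.0
    tracklets = [_make_tracklet(0, 0, 100), _make_tracklet(1, 0, 100),
                 _make_tracklet(2, 110, 90), _make_tracklet(3, 110, 90)]
    feats = {0: _cluster_features(rng, ca), 1: _cluster_features(rng, cb),
             2: _cluster_features(rng, ca), 3: _cluster_features(rng, cb)}
    events = [CrossingEvent(frame_index=110, groups_before=[0, 1],
                            groups_after=[2, 3])]
    out, pooled = stitch_and_accumulate(tracklets, events, feats, cfg)
    assert len(out) == 2
    spans = sorted((tr.start_frame, tr.end_frame) for tr in out)
    assert spans == [(0, 199), (0, 199)]
    # sample pools accumulated (never shrink)
    for tr in out:
        assert len(pooled[tr.id]) == 60


def test_rejected_assignment_is_a_no_op(cfg):
    rng = np.random.default_rng(9)
    shared = _cluster_features(rng, np.zeros(24))
    tracklets = [_make_tracklet(0, 0, 50), _make_tracklet(1, 0, 50),
                 _make_tracklet(2, 60, 50), _make_tracklet(3, 60, 50)]
    feats = {tid: shared.copy() for tid in range(4)}   # indistinguishable
    events = [CrossingEvent(60, [0, 1], [2, 3])]
    out, _ = stitch_and_accumulate(tracklets, events, feats, cfg)
    assert len(out) == 4                # nothing merged


def test_time_overlapping_tracklets_never_merge(cfg):
    rng = np.random.default_rng(10)
    ca = np.zeros(24); ca[0] = 1.0
    cb = np.zeros(24); cb[1] = 1.0
    tracklets = [_make_tracklet(0, 0, 100), _make_tracklet(1, 0, 100),
                 _make_tracklet(2, 90, 60), _make_tracklet(3, 90, 60)]
    feats = {0: _cluster_features(rng, ca), 1: _cluster_features(rng, cb),
             2: _cluster_features(rng, ca), 3: _cluster_features(rng, cb)}
    events = [CrossingEvent(90, [0, 1], [2, 3])]
    out, _ = stitch_and_accumulate(tracklets, events, feats, cfg)
    assert len(out) == 4


# -- final labelling -------------------------------------------------------

def test_reference_group_maximizes_min_length():
    tracklets = [
        Tracklet(id=0, entries=[(t, 0) for t in range(0, 100)]),
        Tracklet(id=1, entries=[(t, 1) for t in range(0, 40)]),
        Tracklet(id=2, entries=[(t, 1) for t in range(50, 200)]),
        Tracklet(id=3, entries=[(t, 0) for t in range(120, 200)]),
    ]
    # frames 0-39 covered by {0,1} (min 40); frames 50-99 by {0,2} (min 100)
    group = _best_reference_group(tracklets, n_fish=2)
    assert sorted(tr.id for tr in group) == [0, 2]


def test_reference_group_error_reports_largest():
    tracklets = [Tracklet(id=0, entries=[(t, 0) for t in range(20)])]
    with pytest.raises(IdentityError, match="largest usable group has 1"):
        _best_reference_group(tracklets, n_fish=3)


def test_no_crossings_trajectories_equal_initial_tracklets(cfg):
    rng = np.random.default_rng(11)
    ca = np.zeros(24); ca[0] = 1.0
    cb = np.zeros(24); cb[1] = 1.0
    tracklets = [_make_tracklet(0, 0, 80), Tracklet(id=1, entries=[(t, 1) for t in range(80)])]
    feats = {0: _cluster_features(rng, ca), 1: _cluster_features(rng, cb)}
    det_info = {(t, j): (float(10 * j), float(t), 0.0)
                for t in range(80) for j in (0, 1)}
    df = final_trajectories(tracklets, feats, det_info, n_fish=2, cfg=cfg)
    assert len(df) == 160
    assert set(df.fish_id.unique()) == {0, 1}
    # conservation: an identity appears at most once per frame
    assert not df.duplicated(subset=["frame", "fish_id"]).any()
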