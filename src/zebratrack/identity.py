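"""Tracklet identity association via texture classifiers.

Two stages of SVM classification stitch the initial tracklets into whole
trajectories:

1. **Per-crossing classifiers.**  For every crossing event the two flanking
   tracklet groups are compared; the group whose *shortest* member is longer
   trains a multi-class SVM (one class per tracklet, samples = its spiral-HOG
   features) and the other group is classified.  A Hungarian assignment on
   the tracklet-vs-class probability matrix links identities across the
   crossing; linked tracklets are merged, accumulating their sample pools.

2. **Final classifier.**  Among groups of tracklets sharing a frame, the one
   whose shortest member is longest (max over groups of min length) defines
   the N reference identities.  A single SVM trained on it labels every
   remaining tracklet, yielding one trajectory per fish.

An assignment is accepted only if every selected probability exceeds 1/N;
accepted matches below ``thr_p`` are flagged for manual review rather than
rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.svm import SVC

from .config import Config
from .tracklets import CrossingEvent, Tracklet

logger = logging.getLogger(__name__)


class IdentityError(ValueError):
    """Raised when identity association cannot proceed (degenerate groups)."""


@dataclass
class Assignment:
    """Result of matching test tracklets to training classes."""

    labels: List[Optional[int]]         # per row: column index or None
    accepted: bool
    flagged_low_confidence: List[int]   # row indices with p < thr_p
    unmatched_classes: List[int]        # columns receiving no row
    probabilities: np.ndarray           # selected p_ij per row
    score: float                        # sum of selected probabilities


def select_training_group(nf_a: Sequence[int], nf_b: Sequence[int]) -> int:
    """0 if group A (with per-tracklet lengths nf_a) trains, else 1.

    The group whose shortest member is longer trains; ties go to the earlier
    group (A) and are logged.
    """
    if not nf_a or not nf_b:
        raise IdentityError("both groups need at least one tracklet")
    min_a, min_b = min(nf_a), min(nf_b)
    if min_a == min_b:
        logger.info("training-group tie (min length %d); choosing the earlier group", min_a)
        return 0
    return 0 if min_a > min_b else 1


def train_group_classifier(features: Dict[int, np.ndarray], cfg: Config) -> SVC:
    """Multi-class probability SVM over one tracklet group.

    ``features`` maps tracklet id -> (n_samples, dim) array.  Every member
    needs at least one sample and there must be at least two classes.
    """
    if len(features) < 2:
        raise IdentityError(f"need >= 2 classes to train, got {len(features)}")
    for tid, f in features.items():
        if f is None or len(f) == 0:
            raise IdentityError(f"tracklet {tid} has no accepted feature samples")
    x = np.vstack([features[tid] for tid in sorted(features)])
    y = np.concatenate([[tid] * len(features[tid]) for tid in sorted(features)])
    clf = SVC(kernel="rbf", C=cfg.svm_c, gamma=cfg.svm_gamma,
              probability=True, random_state=cfg.seed)
    with warnings.catch_warnings():
        # libsvm's pairwise-coupled probability outputs are exactly what the
        # association stage is built on; sklearn deprecates the flag in
        # favour of a wrapper with a different calibration
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(x, y)
    return clf


def classify_tracklet(clf: SVC, features: np.ndarray) -> np.ndarray:
    """Per-class probability row for one tracklet: mean over its frames.

    A tracklet with no features yields a uniform row (and a warning); the row
    is renormalized to sum to 1.
    """
    n_classes = len(clf.classes_)
    if features is None or len(features) == 0:
        logger.warning("tracklet with no features: uniform probability row")
        return np.full(n_classes, 1.0 / n_classes)
    row = clf.predict_proba(features).mean(axis=0)
    return row / row.sum()


def match_groups(p: np.ndarray, n: int, thr_p: float) -> Assignment:
    """Optimal one-to-one assignment of test tracklets (rows) to classes (cols).

    Maximizes the summed probability with no two selections sharing a row or
    column.  The assignment is accepted only if every selected probability is
    strictly greater than 1/n; selected probabilities below ``thr_p`` are
    flagged as low-confidence.  When there are fewer rows than columns, the
    columns left without a row are reported as unmatched classes.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.size == 0:
        raise IdentityError(f"probability matrix must be non-empty 2-D, got shape {p.shape}")
    rows, cols = p.shape
    if rows > cols:
        raise IdentityError(f"more test tracklets ({rows}) than classes ({cols})")
    row_ind, col_ind = linear_sum_assignment(p, maximize=True)
    labels: List[Optional[int]] = [None] * rows
    sel = np.empty(rows)
    for r, c in zip(row_ind, col_ind):
        labels[r] = int(c)
        sel[r] = p[r, c]
    accepted = bool(np.all(sel > 1.0 / n))
    flagged = [int(r) for r in range(rows) if sel[r] < thr_p]
    unmatched = sorted(set(range(cols)) - set(col_ind.tolist()))
    return Assignment(labels=labels, accepted=accepted,
                      flagged_low_confidence=flagged,
                      unmatched_classes=unmatched,
                      probabilities=sel, score=float(sel.sum()))


# -- stitching -------------------------------------------------------------


def _frames_of(tr: Tracklet) -> set:
    return {f for f, _ in tr.entries}


def _merge(a: Tracklet, b: Tracklet) -> Tracklet:
    """Concatenate two tracklets of one identity (disjoint frame spans)."""
    entries = sorted(a.entries + b.entries)
    merged = Tracklet(id=min(a.id, b.id), entries=entries, label=a.label or b.label)
    return merged


def stitch_and_accumulate(
    tracklets: Sequence[Tracklet],
    events: Sequence[CrossingEvent],
    features: Dict[int, np.ndarray],
    cfg: Config,
) -> Tuple[List[Tracklet], Dict[int, np.ndarray]]:
    """Lengthen tracklets by resolving crossings with per-crossing classifiers.

    Events are processed chronologically; sweeps repeat until a full pass
    makes no merge.  A rejected assignment (some probability <= 1/N) leaves
    the tracklets unmerged, to be resolved by the final classifier.  Merged
    tracklets pool their samples, so later classifiers train on more data.
    """
    pool: Dict[int, Tracklet] = {tr.id: tr for tr in tracklets}
    feats: Dict[int, np.ndarray] = {tid: np.asarray(f) for tid, f in features.items()}
    alias: Dict[int, int] = {tr.id: tr.id for tr in tracklets}

    def root(tid: int) -> Optional[int]:
        while tid in alias and alias[tid] != tid:
            tid = alias[tid]
        return tid if tid in pool else None

    changed = True
    sweep = 0
    while changed:
        changed = False
        sweep += 1
        for ev in sorted(events, key=lambda e: e.frame_index):
            before = sorted({r for r in (root(t) for t in ev.groups_before) if r is not None})
            after = sorted({r for r in (root(t) for t in ev.groups_after) if r is not None})
            common = set(before) & set(after)
            before = [t for t in before if t not in common]
            after = [t for t in after if t not in common]
            if len(before) < 2 or len(after) < 1:
                continue
            nf_before = [len(pool[t]) for t in before]
            nf_after = [len(pool[t]) for t in after]
            train_is_before = select_training_group(nf_before, nf_after) == 0
            train_ids = before if train_is_before else after
            test_ids = after if train_is_before else before
            if len(test_ids) > len(train_ids):
                logger.info("event at frame %d: test group larger than training "
                            "group; deferring to the final classifier", ev.frame_index)
                continue
            if len(train_ids) < 2:
                continue
            train_feats = {t: feats.get(t) for t in train_ids}
            try:
                clf = train_group_classifier(train_feats, cfg)
            except IdentityError as exc:
                logger.info("event at frame %d skipped: %s", ev.frame_index, exc)
                continue
            p = np.vstack([classify_tracklet(clf, feats.get(t, np.empty((0, 1))))
                           for t in test_ids])
            assign = match_groups(p, n=len(train_ids), thr_p=cfg.thr_p)
            if not assign.accepted:
                logger.info("event at frame %d: assignment rejected by the 1/N rule",
                            ev.frame_index)
                continue
            for r, test_id in enumerate(test_ids):
                c = assign.labels[r]
                if c is None:
                    continue
                train_id = train_ids[c]
                if _frames_of(pool[test_id]) & _frames_of(pool[train_id]):
                    logger.warning("event at frame %d: refusing to merge "
                                   "time-overlapping tracklets %d/%d",
                                   ev.frame_index, test_id, train_id)
                    continue
                merged = _merge(pool[train_id], pool[test_id])
                fa = feats.pop(train_id, np.empty((0, 1)))
                fb = feats.pop(test_id, np.empty((0, 1)))
                if fa.size and fb.size:
                    fm = np.vstack([fa, fb])
                else:
                    fm = fa if fa.size else fb
                del pool[train_id], pool[test_id]
                pool[merged.id] = merged
                feats[merged.id] = fm
                alias[train_id] = merged.id
                alias[test_id] = merged.id
                alias[merged.id] = merged.id
                changed = True
    logger.info("stitching converged after %d sweep(s); %d lengthened tracklets",
                sweep, len(pool))
    out = sorted(pool.values(), key=lambda tr: (tr.start_frame, tr.id))
    return out, feats


# -- final labelling -------------------------------------------------------


def _best_reference_group(tracklets: Sequence[Tracklet], n_fish: int
                          ) -> List[Tracklet]:
    """The tracklet group sharing a frame whose shortest member is longest."""
    by_frame: Dict[int, List[Tracklet]] = {}
    for tr in tracklets:
        for f, _ in tr.entries:
            by_frame.setdefault(f, []).append(tr)
    best: Optional[List[Tracklet]] = None
    best_score = -1
    largest = 0
    for f, group in by_frame.items():
        largest = max(largest, len(group))
        if len(group) != n_fish:
            continue
        score = min(len(tr) for tr in group)
        if score > best_score:
            best_score = score
            best = group
    if best is None:
        raise IdentityError(
            f"no frame is covered by exactly {n_fish} tracklets "
            f"(largest usable group has {largest})")
    return sorted(best, key=lambda tr: tr.id)


def final_trajectories(
    tracklets: Sequence[Tracklet],
    features: Dict[int, np.ndarray],
    det_info: Dict[Tuple[int, int], Tuple[float, float, float]],
    n_fish: int,
    cfg: Config,
) -> pd.DataFrame:
    """Label every tracklet with one of N identities and emit trajectories.

    ``det_info`` maps (frame, detection index) to (x, y, heading_deg).
    Returns a table with columns frame, fish_id, x, y, heading_deg,
    confidence, flagged; frames a fish spends occluded are absent (gaps).
    """
    reference = _best_reference_group(tracklets, n_fish)
    ref_ids = [tr.id for tr in reference]
    identity_of: Dict[int, Tuple[int, float]] = {
        tid: (k, 1.0) for k, tid in enumerate(ref_ids)}

    remaining = [tr for tr in tracklets if tr.id not in identity_of]
    if remaining:
        clf = train_group_classifier({t: features[t] for t in ref_ids}, cfg)
        class_to_identity = {tid: k for k, tid in enumerate(ref_ids)}
        col_identity = [class_to_identity[c] for c in clf.classes_]
        scored = []
        for tr in remaining:
            row = classify_tracklet(clf, features.get(tr.id, np.empty((0, 1))))
            k = int(np.argmax(row))
            scored.append((float(row[k]), tr, col_identity[k]))
        # confident tracklets claim identities first; clashes stay unlabelled
        frames_used: Dict[int, set] = {
            k: _frames_of(tr) for k, tr in zip(range(n_fish), reference)}
        for p_best, tr, k in sorted(scored, key=lambda s: -s[0]):
            if p_best <= 1.0 / n_fish:
                logger.info("tracklet %d left unlabelled (p=%.3f <= 1/N)", tr.id, p_best)
                continue
            fset = _frames_of(tr)
            if fset & frames_used.get(k, set()):
                logger.info("tracklet %d: identity %d already present on its "
                            "frames; left unlabelled", tr.id, k)
                continue
            identity_of[tr.id] = (k, p_best)
            frames_used.setdefault(k, set()).update(fset)

    records = []
    for tr in tracklets:
        if tr.id not in identity_of:
            continue
        k, conf = identity_of[tr.id]
        flagged = conf < cfg.thr_p
        for f, j in tr.entries:
            x, y, heading = det_info[(f, j)]
            records.append((f, k, x, y, heading, conf, flagged))
    df = pd.DataFrame.from_records(
        records, columns=["frame", "fish_id", "x", "y", "heading_deg",
                          "confidence", "flagged"])
    return df.sort_values(["frame", "fish_id"]).reset_index(drop=True)
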