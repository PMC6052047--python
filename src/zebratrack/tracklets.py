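"""Initial tracklets: minimum-distance frame-to-frame matching with crossing logic.

Fish displacement between consecutive frames is small, so each object on
frame t-1 is matched to its nearest object on frame t.  Two rules handle the
failure modes:

* when two previous objects share a nearest neighbour the pair is ambiguous
  and both matches are dropped — unless no crossing is indicated (object
  counts unchanged) and the closer candidate wins by more than ``thr_d`` px,
  in which case it is reinstated (a stationary fish or a coincidental
  distance, not an overlap);
* a change in object count flags a crossing at that transition.

Chains of matches become tracklets.  Merged-blob tracklets (started by an
ambiguous match or by a detection far larger than its neighbours) are
overlap-marked: they are cut at the next crossing transition so they can
never carry an identity across a split, and they are dropped from the output.
Tracklets shorter than ``min_tracklet_len`` frames are crossing debris and
are discarded as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .config import Config
from .detection import Detection

logger = logging.getLogger(__name__)


@dataclass
class Tracklet:
    """Gap-free detection chain of (presumably) one individual."""

    id: int
    entries: List[Tuple[int, int]] = field(default_factory=list)  # (frame, det index)
    label: Optional[int] = None
    overlap: bool = False       # started from a merged blob

    @property
    def start_frame(self) -> int:
        return self.entries[0][0]

    @property
    def end_frame(self) -> int:
        return self.entries[-1][0]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CrossingEvent:
    """One crossing: the tracklets it ended and the tracklets it spawned."""

    frame_index: int
    groups_before: List[int]
    groups_after: List[int]


def crossing_flag(n_prev: int, n_curr: int) -> int:
    """1 when the object count changed between the frames (a crossing), else 0."""
    if n_prev < 0 or n_curr < 0:
        raise ValueError("object counts must be non-negative")
    return 0 if n_prev == n_curr else 1


def match_frame(prev: Sequence[Tuple[float, float]],
                curr: Sequence[Tuple[float, float]],
                cfg: Config) -> Tuple[np.ndarray, Set[int]]:
    """Nearest-neighbour match flags between consecutive frames.

    Implements the minimum-distance rule, the ambiguity cancellation, and the
    ``thr_d`` reinstatement.  A shared nearest neighbour is treated as the
    stationary-fish / coincidental-distance situation rather than a crossing,
    so the closer candidate is reinstated whenever it wins by more than
    ``thr_d``.  Ties in the argmin are broken toward the lowest candidate
    index.  Matches beyond ``max_match_dist`` are suppressed.

    Returns
    -------
    m : bool array (n_prev, n_curr)
        ``m[i, j]`` true iff object i on the earlier frame matches object j.
    conflict_cols : set of int
        Current-frame objects left with an unresolved shared-nearest-
        neighbour ambiguity — the merged-blob signature.  A conflict settled
        by the ``thr_d`` margin is not reported.
    """
    n_prev, n_curr = len(prev), len(curr)
    m = np.zeros((n_prev, n_curr), dtype=bool)
    if n_prev == 0 or n_curr == 0:
        return m, set()
    p = np.asarray(prev, dtype=float)
    c = np.asarray(curr, dtype=float)
    d = np.hypot(p[:, None, 0] - c[None, :, 0], p[:, None, 1] - c[None, :, 1])
    nearest = np.argmin(d, axis=1)      # lowest index wins ties
    conflict_cols = set()
    for j in range(n_curr):
        rows = np.nonzero(nearest == j)[0]
        rows = rows[d[rows, j] <= cfg.max_match_dist]
        if rows.size == 1:
            m[rows[0], j] = True
        elif rows.size >= 2:
            # ambiguous: all dropped, unless the closest candidate wins by a
            # clear thr_d margin over the runner-up (the stationary-fish /
            # coincidental-distance case, which is not a merge)
            order = rows[np.argsort(d[rows, j], kind="stable")]
            if d[order[1], j] - d[order[0], j] > cfg.thr_d:
                m[order[0], j] = True
            else:
                conflict_cols.add(int(j))
    return m, conflict_cols


def _merged_suspects(prev_dets: Sequence[Detection],
                     curr_dets: Sequence[Detection],
                     cfg: Config) -> Set[int]:
    """Current detections whose area marks them as merged blobs."""
    if not prev_dets or not curr_dets:
        return set()
    med = float(np.median([det.area for det in prev_dets]))
    return {j for j, det in enumerate(curr_dets)
            if det.area > cfg.merge_area_factor * med}


def build_tracklets(detections: Sequence[Sequence[Detection]],
                    cfg: Config) -> Tuple[List[Tracklet], List[CrossingEvent]]:
    """Chain per-frame detections into pure per-identity tracklets.

    Parameters
    ----------
    detections : list over frames of lists of :class:`Detection`.

    Returns
    -------
    tracklets : surviving tracklets (overlap-marked and shorter-than-minimum
        chains removed), ordered by start frame.
    events : crossing events pairing the tracklets that ended just before a
        crossing with those that started when it resolved.
    """
    next_id = 0
    active: Dict[int, Tracklet] = {}        # det index on latest frame -> tracklet
    finished: List[Tracklet] = []
    pending: List[Tracklet] = []            # cleanly ended, waiting for an event
    events: List[CrossingEvent] = []
    last_pos: Dict[int, Tuple[float, float]] = {}   # tracklet id -> last centroid

    def close(tr: Tracklet) -> None:
        finished.append(tr)
        if not tr.overlap:
            pending.append(tr)

    for t, frame_dets in enumerate(detections):
        curr_pos = [det.centroid for det in frame_dets]
        if t == 0:
            new_active = {}
            for j in range(len(frame_dets)):
                tr = Tracklet(id=next_id, entries=[(0, j)])
                next_id += 1
                new_active[j] = tr
                last_pos[tr.id] = curr_pos[j]
            active = new_active
            continue

        prev_dets = detections[t - 1]
        prev_pos = [det.centroid for det in prev_dets]
        m, conflicts = match_frame(prev_pos, curr_pos, cfg)
        flag = crossing_flag(len(prev_dets), len(frame_dets))
        suspects = conflicts | _merged_suspects(prev_dets, frame_dets, cfg)

        new_active: Dict[int, Tracklet] = {}
        matched_curr: Set[int] = set()
        for i, tr in active.items():
            js = np.nonzero(m[i])[0]
            j = int(js[0]) if js.size else None
            sever = j is not None and (
                (tr.overlap and flag == 1)      # merged blob at a crossing
                or j in suspects)               # match into a merged blob
            if j is not None and not sever:
                tr.entries.append((t, j))
                new_active[j] = tr
                matched_curr.add(j)
                last_pos[tr.id] = curr_pos[j]
            else:
                close(tr)

        started_clean: List[Tracklet] = []
        for j in range(len(frame_dets)):
            if j in matched_curr:
                continue
            tr = Tracklet(id=next_id, entries=[(t, j)],
                          overlap=j in suspects)
            next_id += 1
            new_active[j] = tr
            last_pos[tr.id] = curr_pos[j]
            if not tr.overlap:
                started_clean.append(tr)
        active = new_active

        # pair cleanly ended tracklets with the clean starters near them
        if started_clean and pending:
            start_pos = [last_pos[tr.id] for tr in started_clean]
            before: List[Tracklet] = []
            still_pending: List[Tracklet] = []
            for tr in pending:
                ex, ey = last_pos[tr.id]
                near = any(np.hypot(ex - sx, ey - sy) <= cfg.max_match_dist
                           for sx, sy in start_pos)
                (before if near else still_pending).append(tr)
            if before:
                events.append(CrossingEvent(
                    frame_index=t,
                    groups_before=[tr.id for tr in before],
                    groups_after=[tr.id for tr in started_clean],
                ))
            pending = still_pending

    for tr in active.values():
        finished.append(tr)

    kept = [tr for tr in finished
            if not tr.overlap and len(tr) >= cfg.min_tracklet_len]
    kept.sort(key=lambda tr: (tr.start_frame, tr.id))
    kept_ids = {tr.id for tr in kept}
    filtered_events = []
    for ev in events:
        before = [tid for tid in ev.groups_before if tid in kept_ids]
        after = [tid for tid in ev.groups_after if tid in kept_ids]
        if before and after:
            filtered_events.append(CrossingEvent(ev.frame_index, before, after))
    logger.info("built %d tracklets (%d raw), %d crossing events",
                len(kept), len(finished), len(filtered_events))
    return kept, filtered_events
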