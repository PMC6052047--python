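"""Tracking evaluation metrics and shoaling/locomotion descriptors.

Evaluation compares emitted trajectories against ground truth after fixing
the identity correspondence by majority frame overlap (a Hungarian assignment
on per-pair agreement counts).  With F fish and T processed frames:

* IA (identifying accuracy) — correctly identified fish / identified fish;
* CA (classification accuracy) — correctly labelled frames / classified frames;
* CrossFrequency — frames where fewer than F fish were detected / T;
* AccuracyRate — 1 − wrongly tracked frames / T;
* MissRate — missed frames / (F · T);
* ErrorRate — wrongly tracked frames / (F · T).

"Processed frames" is used as the tracked-frames denominator throughout.

The behaviour descriptors are the standard shoaling statistics: per-fish
nearest-neighbour distance and the mean over all unordered pairs of the
inter-individual distance, sampled at a fixed interval, plus per-fish
locomotion measures (path length, mean speed, cumulative absolute turn,
angular velocity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Tracking quality metrics, all fractions in [0, 1]."""

    ia: float
    ca: float
    cross_frequency: float
    accuracy_rate: float
    miss_rate: float
    error_rate: float
    n_fish: int
    n_frames: int
    identity_map: Dict[int, int] = field(default_factory=dict)  # pred -> truth
    per_fish_correct: Dict[int, int] = field(default_factory=dict)
    per_fish_wrong: Dict[int, int] = field(default_factory=dict)
    per_fish_missed: Dict[int, int] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        return {"IA": self.ia, "CA": self.ca,
                "CrossFrequency": self.cross_frequency,
                "AccuracyRate": self.accuracy_rate,
                "MissRate": self.miss_rate, "ErrorRate": self.error_rate}


def _nearest_truth(truth_pos: Dict[int, Dict[int, Tuple[float, float]]],
                   frame: int, x: float, y: float) -> Optional[int]:
    """Ground-truth fish closest to (x, y) on the given frame."""
    best, best_d = None, np.inf
    for fish, pos in truth_pos.get(frame, {}).items():
        d = np.hypot(pos[0] - x, pos[1] - y)
        if d < best_d:
            best, best_d = fish, d
    return best


def evaluate(trajectories: pd.DataFrame, truth: pd.DataFrame,
             total_fish: int,
             detected_per_frame: Optional[Dict[int, int]] = None
             ) -> EvaluationReport:
    """Score trajectories against ground truth.

    ``trajectories`` needs columns frame, fish_id, x, y; ``truth`` needs
    frame, fish, x, y.  ``detected_per_frame`` optionally supplies the raw
    per-frame detection counts for CrossFrequency; otherwise the number of
    trajectory points per frame stands in for it.
    """
    frames = sorted(truth["frame"].unique())
    n_frames = len(frames)
    if trajectories.empty:
        warnings.warn("empty trajectories: returning an all-zero report")
        return EvaluationReport(0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                                total_fish, n_frames)

    truth_pos: Dict[int, Dict[int, Tuple[float, float]]] = {}
    for row in truth.itertuples(index=False):
        truth_pos.setdefault(int(row.frame), {})[int(row.fish)] = (row.x, row.y)

    pred_ids = sorted(trajectories["fish_id"].unique())
    truth_ids = sorted(truth["fish"].unique())
    # per-frame nearest truth fish for every trajectory point
    nearest: Dict[Tuple[int, int], int] = {}
    overlap = np.zeros((len(pred_ids), len(truth_ids)), dtype=int)
    p_index = {p: i for i, p in enumerate(pred_ids)}
    t_index = {g: i for i, g in enumerate(truth_ids)}
    for row in trajectories.itertuples(index=False):
        g = _nearest_truth(truth_pos, int(row.frame), row.x, row.y)
        if g is None:
            continue
        nearest[(int(row.frame), int(row.fish_id))] = g
        overlap[p_index[int(row.fish_id)], t_index[g]] += 1

    # identity correspondence: majority overlap, one-to-one
    rows, cols = linear_sum_assignment(overlap, maximize=True)
    identity_map = {pred_ids[r]: truth_ids[c] for r, c in zip(rows, cols)
                    if overlap[r, c] > 0}

    per_correct = {p: 0 for p in pred_ids}
    per_wrong = {p: 0 for p in pred_ids}
    for (frame, p), g in nearest.items():
        if identity_map.get(p) == g:
            per_correct[p] += 1
        else:
            per_wrong[p] += 1
    classified = {p: per_correct[p] + per_wrong[p] for p in pred_ids}
    assigned_frames = sum(classified.values())
    per_missed = {p: n_frames - classified[p] for p in pred_ids}
    # fish with no trajectory at all are fully missed
    missing_fish = max(0, total_fish - len(pred_ids))
    total_missed = sum(per_missed.values()) + missing_fish * n_frames

    sum_wrong = sum(per_wrong.values())
    sum_correct = sum(per_correct.values())

    if detected_per_frame is None:
        counts = trajectories.groupby("frame").size()
        detected_per_frame = {int(f): int(c) for f, c in counts.items()}
    crossing_frames = sum(1 for f in frames
                          if detected_per_frame.get(int(f), 0) < total_fish)

    identified = [p for p in pred_ids if p in identity_map]
    correct_identified = [p for p in identified
                          if per_correct[p] > per_wrong[p]]

    denom_ff = total_fish * n_frames
    report = EvaluationReport(
        ia=len(correct_identified) / len(identified) if identified else 0.0,
        ca=sum_correct / assigned_frames if assigned_frames else 0.0,
        cross_frequency=crossing_frames / n_frames if n_frames else 0.0,
        accuracy_rate=1.0 - sum_wrong / n_frames if n_frames else 0.0,
        miss_rate=total_missed / denom_ff if denom_ff else 0.0,
        error_rate=sum_wrong / denom_ff if denom_ff else 0.0,
        n_fish=total_fish,
        n_frames=n_frames,
        identity_map=identity_map,
        per_fish_correct=per_correct,
        per_fish_wrong=per_wrong,
        per_fish_missed=per_missed,
    )
    return report


def shoal_stats(trajectories: pd.DataFrame, sampling_interval: float,
                frame_rate: float) -> pd.DataFrame:
    """Nearest-neighbour and mean inter-individual distances at sampled frames.

    Frames are sampled every ``sampling_interval`` seconds.  Frames with
    fewer than two fish present are skipped (and logged).  Returns one row
    per (sampled frame, fish) with the fish's nearest-neighbour distance and
    the frame-level mean pairwise distance.
    """
    if sampling_interval <= 0 or frame_rate <= 0:
        raise ValueError("sampling_interval and frame_rate must be positive")
    step = max(int(round(sampling_interval * frame_rate)), 1)
    frames = sorted(trajectories["frame"].unique())
    records = []
    for f in frames[::1]:
        if (f - frames[0]) % step != 0:
            continue
        sub = trajectories[trajectories["frame"] == f]
        if len(sub) < 2:
            logger.info("frame %d skipped: fewer than 2 fish present", f)
            continue
        pts = sub[["x", "y"]].to_numpy(dtype=float)
        ids = sub["fish_id"].to_numpy()
        d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                     pts[:, None, 1] - pts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        nnd = d.min(axis=1)
        iu = np.triu_indices(len(pts), k=1)
        mean_iid = float(d[iu].mean())
        for fish, dist in zip(ids, nnd):
            records.append((f, int(fish), float(dist), mean_iid))
    return pd.DataFrame.from_records(
        records, columns=["frame", "fish_id", "nnd", "mean_iid"])


def _wrap_deg(delta: np.ndarray) -> np.ndarray:
    """Wrap heading changes to (-180, 180]."""
    return 180.0 - np.mod(180.0 - delta, 360.0)


def locomotion_stats(trajectory: pd.DataFrame, frame_rate: float
                     ) -> Dict[str, float]:
    """Path length, mean speed, cumulative turn and angular velocity.

    ``trajectory`` is one fish's table with columns frame, x, y and
    optionally heading_deg; needs at least 2 rows.  Gaps split the track into
    segments scored independently; gap spans contribute neither distance nor
    duration.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if len(trajectory) < 2:
        raise ValueError("need at least 2 frames")
    tr = trajectory.sort_values("frame")
    frames = tr["frame"].to_numpy(dtype=int)
    xs = tr["x"].to_numpy(dtype=float)
    ys = tr["y"].to_numpy(dtype=float)
    heading = (tr["heading_deg"].to_numpy(dtype=float)
               if "heading_deg" in tr.columns else None)
    breaks = np.nonzero(np.diff(frames) != 1)[0]
    segments = np.split(np.arange(len(frames)), breaks + 1)
    distance = 0.0
    turn = 0.0
    duration = 0.0
    for seg in segments:
        if len(seg) < 2:
            continue
        sx, sy = xs[seg], ys[seg]
        distance += float(np.hypot(np.diff(sx), np.diff(sy)).sum())
        duration += (len(seg) - 1) / frame_rate
        if heading is not None:
            turn += float(np.abs(_wrap_deg(np.diff(heading[seg]))).sum())
    return {
        "total_distance": distance,
        "average_velocity": distance / duration if duration else 0.0,
        "turn_angle": turn,
        "angular_velocity": turn / duration if duration else 0.0,
    }
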