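"""End-to-end tracking pipeline: frames in, per-identity trajectories out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import Config
from .detection import BackgroundModel, Detection, build_background, segment_frame
from .hog import extract_feature
from .identity import final_trajectories, stitch_and_accumulate
from .metrics import EvaluationReport, evaluate
from .roi import FishROI, extract_roi, full_angle, resolve_head
from .tracklets import CrossingEvent, Tracklet, build_tracklets

logger = logging.getLogger(__name__)


@dataclass
class TrackingResult:
    """Everything the pipeline produced, plus per-stage counters."""

    trajectories: pd.DataFrame
    tracklets: List[Tracklet]
    events: List[CrossingEvent]
    background: BackgroundModel
    report: Optional[EvaluationReport] = None
    counters: Dict[str, int] = field(default_factory=dict)


def run_pipeline(frames: Sequence[np.ndarray], cfg: Config,
                 n_fish: Optional[int] = None,
                 truth: Optional[pd.DataFrame] = None) -> TrackingResult:
    """Track all fish through a frame sequence.

    Stages: background model → per-frame segmentation → head-right ROI and
    spiral-HOG feature per detection → initial tracklets → per-crossing
    stitching → final classifier → trajectory table.  Deterministic given the
    config (including its seed).

    ``n_fish`` defaults to the modal per-frame detection count.  When
    ``truth`` (columns frame, fish, x, y) is given, an evaluation report is
    attached.
    """
    if len(frames) == 0:
        raise ValueError("no frames to process")
    f_bg = min(cfg.f_background, len(frames))
    bg = build_background(frames, f_bg)

    detections: List[List[Detection]] = []
    rois: List[List[FishROI]] = []
    features: Dict[Tuple[int, int], np.ndarray] = {}
    det_info: Dict[Tuple[int, int], Tuple[float, float, float]] = {}
    n_rejected = 0
    for t, frame in enumerate(frames):
        dets = segment_frame(frame, bg, cfg, frame_index=t)
        frame_rois: List[FishROI] = []
        for j, det in enumerate(dets):
            phead = resolve_head(frame, det)
            theta_full = full_angle(det.theta_raw, phead)
            roi = extract_roi(frame, det, theta_full, cfg, bg)
            frame_rois.append(roi)
            det_info[(t, j)] = (det.centroid[0], det.centroid[1], theta_full)
            if roi.accepted:
                features[(t, j)] = extract_feature(roi, bg, cfg).vector
            else:
                n_rejected += 1
        detections.append(dets)
        rois.append(frame_rois)
    n_detections = sum(len(d) for d in detections)
    if n_detections == 0:
        raise ValueError("no detections in the whole sequence; check thr_s/thr_g")

    if n_fish is None:
        counts = [len(d) for d in detections if d]
        n_fish = int(np.bincount(counts).argmax())
        logger.info("inferred n_fish = %d from detection counts", n_fish)

    tracklets, events = build_tracklets(detections, cfg)
    tracklet_features: Dict[int, np.ndarray] = {}
    for tr in tracklets:
        feats = [features[(f, j)] for f, j in tr.entries if (f, j) in features]
        tracklet_features[tr.id] = (np.vstack(feats) if feats
                                    else np.empty((0, 1)))

    lengthened, pooled = stitch_and_accumulate(tracklets, events,
                                               tracklet_features, cfg)
    trajectories = final_trajectories(lengthened, pooled, det_info,
                                      n_fish, cfg)

    report = None
    if truth is not None:
        detected_per_frame = {t: len(d) for t, d in enumerate(detections)}
        report = evaluate(trajectories, truth, total_fish=n_fish,
                          detected_per_frame=detected_per_frame)

    counters = {
        "frames": len(frames),
        "detections": n_detections,
        "rejected_rois": n_rejected,
        "tracklets": len(tracklets),
        "crossings": len(events),
        "lengthened_tracklets": len(lengthened),
        "flagged_frames": int(trajectories["flagged"].sum()) if len(trajectories) else 0,
    }
    logger.info("pipeline counters: %s", counters)
    return TrackingResult(trajectories=trajectories, tracklets=tracklets,
                          events=events, background=bg, report=report,
                          counters=counters)
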