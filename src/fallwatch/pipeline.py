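"""End-to-end pipeline: frames -> silhouettes -> features -> postures -> fall events."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from math import isinf
from pathlib import Path

import numpy as np
import pandas as pd

from .background import build_background_model
from .classifier import predict_posture
from .config import PipelineConfig
from .descriptor import feature_vector
from .rules import FallDecision, FrameState, detect_fall
from .silhouette import SilhouetteExtractor

__all__ = ["EventReport", "extract_silhouettes", "run_pipeline"]

log = logging.getLogger("fallwatch")

SCHEMA_VERSION = 1


@dataclass
class EventReport:
    video_id: str
    n_frames: int
    decisions: list[FallDecision] = field(repr=False)
    events: list[dict]

    def to_json_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "video_id": self.video_id,
            "n_frames": self.n_frames,
            "events": self.events,
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))

    def trace_frame(self) -> pd.DataFrame:
        rows = [
            {
                "frame": d.frame_index,
                "posture": d.posture,
                "coverage": round(d.coverage, 6),
                "motion": round(d.motion, 6),
                "rule_abnormal": d.rule_abnormal,
                "rule_floor": d.rule_floor,
                "rule_transition": d.rule_transition,
                "rule_inactive": d.rule_inactive,
                "verdict": d.verdict,
            }
            for d in self.decisions
        ]
        return pd.DataFrame(rows)

    def write_trace(self, path) -> None:
        self.trace_frame().to_csv(path, index=False)


def extract_silhouettes(
    frames, config: PipelineConfig
) -> list[np.ndarray | None]:
    """Run background training + per-frame extraction over a frame list.

    The first ``n_train`` frames train the background model and yield no
    silhouette (None entries); later frames without a plausible person blob
    are also None.
    """
    ext = config.extraction
    model = build_background_model(frames, ext.n_train, ext.tolerance_floor)
    extractor = SilhouetteExtractor(
        model,
        shadow_params=config.shadow,
        min_blob_area=ext.min_blob_area,
        merge_distance=ext.merge_distance,
    )
    masks: list[np.ndarray | None] = [None] * ext.n_train
    for frame in frames[ext.n_train :]:
        result = extractor.process(frame)
        masks.append(result[0] if result is not None else None)
    log.info(
        "extracted %d/%d silhouettes",
        sum(m is not None for m in masks),
        len(frames),
    )
    return masks


def run_pipeline(
    masks,
    floor: np.ndarray,
    model,
    config: PipelineConfig | None = None,
    video_id: str = "video",
) -> EventReport:
    """Classify each silhouette and run the fall rules.

    ``masks`` is a per-frame list of boolean silhouettes (None where no
    person was found, e.g. during background training).  ``floor`` is the
    floor mask and ``model`` a trained posture SVM.
    """
    config = config or PipelineConfig()
    if floor is None or not np.asarray(floor).any():
        raise ValueError("floor mask required")
    stream: list[FrameState] = []
    for t, mask in enumerate(masks):
        if mask is None or not mask.any():
            # No person this frame: neutral record that breaks any window.
            stream.append(FrameState(frame_index=t, posture=0, coverage=0.0, motion=1.0))
            continue
        fs = feature_vector(mask, n=config.descriptor_n)
        posture = int(predict_posture(model, fs))
        stream.append(FrameState(frame_index=t, posture=posture, mask=mask))
    decisions = detect_fall(stream, floor=floor, params=config.rules)
    events = [
        {
            "frame": d.frame_index,
            "transition_frames": None if isinf(d.transition_frames) else int(d.transition_frames),
            "coverage": round(d.coverage, 4),
            "rules": {
                "abnormal": d.rule_abnormal,
                "floor": d.rule_floor,
                "transition": d.rule_transition,
                "inactive": d.rule_inactive,
            },
        }
        for d in decisions
        if d.verdict == "fall"
    ]
    log.info("%s: %d frames, %d fall event(s)", video_id, len(masks), len(events))
    return EventReport(
        video_id=video_id,
        n_frames=len(masks),
        decisions=decisions,
        events=events,
    )
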