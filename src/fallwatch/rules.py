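"""Rule-based fall confirmation over a per-frame posture/mask stream.

A fall is declared only when four conditions line up:

1. *Abnormal posture* — the frame is classified lie or bend.
2. *Floor coverage* — at least 85% of the silhouette's pixels lie inside the
   manually drawn floor region (a fall ends on the floor; lying on a sofa
   does not).
3. *Fast transition* — few frames (<= 25, about one second at 25 fps) have
   passed since the person was last seen standing or sitting.  Deliberately
   lying down takes much longer (> 80 frames), which is what separates the
   two.
4. *Inactivity* — the fallen posture then persists essentially motionless
   for at least 25 consecutive frames.  Stillness is tested two ways: the
   frame-to-frame silhouette change (1 - IoU between consecutive masks) must
   stay below ``motion_epsilon``, and, when masks are available, the
   silhouette must also stay within ``settle_epsilon`` of the *anchor* mask
   captured when the inactivity window opened.  The anchor test is what
   separates true stillness from slow creep: a person lowering themselves
   gradually moves little between any two frames but drifts far from the
   anchor within a few frames, which resets the window.

The transition test is evaluated when the inactivity window opens and holds
for that window; the window itself keeps counting only while posture, floor
coverage and stillness persist, and resets otherwise.  One episode (from
abnormal onset until the person is next seen standing/sitting) can raise at
most one alarm.  If no stand/sit frame was ever observed — the person
entered the scene already down — the transition rule fails and no alarm is
possible (conservative behaviour).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classifier import ABNORMAL_POSTURES, POSTURE_CODES

__all__ = [
    "FallRuleParams",
    "FrameState",
    "FallDecision",
    "floor_coverage",
    "motion_score",
    "transition_frames",
    "detect_fall",
]

STAND_SIT = frozenset({POSTURE_CODES["stand"], POSTURE_CODES["sit"]})


@dataclass(frozen=True)
class FallRuleParams:
    coverage_threshold: float = 0.85  # min fraction of silhouette on the floor
    transition_max: int = 25  # frames; fall-speed posture change
    inactivity_min: int = 25  # frames; how long stillness must persist
    fps: float = 25.0  # so transition_max/inactivity_min = 1 s
    motion_epsilon: float = 0.05  # max consecutive-frame 1-IoU for "no motion"
    settle_epsilon: float = 0.10  # max 1-IoU drift from the window anchor mask

    def __post_init__(self) -> None:
        if not (0 < self.coverage_threshold <= 1):
            raise ValueError("coverage_threshold must lie in (0, 1]")
        if self.transition_max <= 0 or self.inactivity_min <= 0:
            raise ValueError("frame thresholds must be positive")


@dataclass
class FrameState:
    """Per-frame record entering the rule engine.

    ``coverage`` and ``motion`` may be supplied directly (e.g. in unit tests)
    or left None to be computed from ``mask`` and the floor mask.
    """

    frame_index: int
    posture: int
    coverage: float | None = None
    motion: float | None = None
    mask: np.ndarray | None = None


@dataclass
class FallDecision:
    frame_index: int
    posture: int
    coverage: float
    motion: float
    rule_abnormal: bool
    rule_floor: bool
    rule_transition: bool
    rule_inactive: bool
    verdict: str  # "fall" | "no_fall"
    transition_frames: float  # frames since last stand/sit (inf if never seen)


def floor_coverage(mask: np.ndarray, floor: np.ndarray) -> float:
    """Fraction of silhouette pixels lying inside the floor region."""
    mask = np.asarray(mask, dtype=bool)
    floor = np.asarray(floor, dtype=bool)
    if mask.shape != floor.shape:
        raise ValueError("dimension mismatch between mask and floor")
    m = mask.sum()
    if m == 0:
        raise ValueError("empty silhouette")
    return float((mask & floor).sum() / m)


def motion_score(mask_t: np.ndarray, mask_prev: np.ndarray) -> float:
    """Silhouette change between consecutive frames: 1 - IoU (0 = identical)."""
    a = np.asarray(mask_t, dtype=bool)
    b = np.asarray(mask_prev, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch between masks")
    union = (a | b).sum()
    if union == 0:
        return 0.0
    return float((a ^ b).sum() / union)


def transition_frames(history, current: int) -> float:
    """Frames between ``current`` and the latest stand/sit frame before it.

    Returns ``inf`` when no stand/sit frame exists up to ``current``.
    """
    last = None
    for state in history:
        if state.frame_index > current:
            break
        if state.posture in STAND_SIT:
            last = state.frame_index
    if last is None:
        return math.inf
    return float(current - last)


def _resolve(state: FrameState, floor: np.ndarray | None, prev_mask) -> tuple[float, float]:
    coverage = state.coverage
    if coverage is None:
        if state.mask is None or floor is None:
            raise ValueError("FrameState needs either coverage or a mask + floor")
        coverage = floor_coverage(state.mask, floor)
    motion = state.motion
    if motion is None:
        if state.mask is None:
            raise ValueError("FrameState needs either motion or a mask")
        motion = 0.0 if prev_mask is None else motion_score(state.mask, prev_mask)
    return coverage, motion


def detect_fall(
    stream,
    floor: np.ndarray | None = None,
    params: FallRuleParams | None = None,
) -> list[FallDecision]:
    """Run the four-rule engine over an ordered frame stream.

    Returns one :class:`FallDecision` per frame; ``verdict == "fall"`` marks
    the single frame at which each fall episode is confirmed.
    """
    params = params or FallRuleParams()
    stream = list(stream)
    if not stream:
        raise ValueError("empty stream")

    decisions: list[FallDecision] = []
    last_stand_sit: int | None = None
    prev_mask = None
    window_open = False  # inactivity window armed by rules 1-3
    window_transition = math.inf  # latched transition count for the window
    window_count = 0
    anchor_mask = None  # silhouette at window opening (settledness reference)
    episode_fired = False

    for state in stream:
        coverage, motion = _resolve(state, floor, prev_mask)
        posture = state.posture
        abnormal = posture in ABNORMAL_POSTURES
        floor_ok = coverage >= params.coverage_threshold
        if posture in STAND_SIT:
            last_stand_sit = state.frame_index
            episode_fired = False  # back upright: re-arm for the next episode
        tf = (
            math.inf
            if last_stand_sit is None
            else float(state.frame_index - last_stand_sit)
        )
        still = motion <= params.motion_epsilon
        settled = (
            still
            and window_open
            and (
                anchor_mask is None
                or state.mask is None
                or motion_score(state.mask, anchor_mask) <= params.settle_epsilon
            )
        )

        if settled and abnormal and floor_ok:
            window_count += 1
        elif abnormal and floor_ok and still and tf <= params.transition_max:
            window_open = True
            window_transition = tf
            window_count = 1
            anchor_mask = state.mask
        else:
            window_open = False
            window_count = 0
            window_transition = math.inf
            anchor_mask = None

        rule_transition = (
            window_transition <= params.transition_max
            if window_open
            else tf <= params.transition_max
        )
        rule_inactive = (
            window_open and window_count >= params.inactivity_min and not episode_fired
        )
        fall_now = abnormal and floor_ok and rule_transition and rule_inactive
        if fall_now:
            episode_fired = True
        decisions.append(
            FallDecision(
                frame_index=state.frame_index,
                posture=posture,
                coverage=coverage,
                motion=motion,
                rule_abnormal=abnormal,
                rule_floor=floor_ok,
                rule_transition=rule_transition,
                rule_inactive=rule_inactive,
                verdict="fall" if fall_now else "no_fall",
                transition_frames=window_transition if window_open else tf,
            )
        )
        if state.mask is not None:
            prev_mask = state.mask
    return decisions
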