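import itertools
import math

import numpy as np
import pytest

from fallwatch.classifier import POSTURE_CODES
from fallwatch.rules import (
    FallRuleParams,
    FrameState,
    detect_fall,
    floor_coverage,
    motion_score,
    transition_frames,
)

BEND, LIE, SIT, STAND = 1, 2, 3, 4


class TestFloorCoverage:
    def test_containment_split_and_empty_floor(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10:14, 5:15] = True
        floor = np.zeros_like(mask)
        floor[8:, :] = True
        assert floor_coverage(mask, floor) == 1.0
        half = np.zeros_like(mask)
        half[12:, :] = True  # covers rows 12,13 of the 4-row mask
        assert floor_coverage(mask, half) == 0.5
        assert floor_coverage(mask, np.zeros_like(mask)) == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty silhouette"):
            floor_coverage(np.zeros((5, 5), dtype=bool), np.ones((5, 5), dtype=bool))


class TestMotionScore:
    def test_identical_disjoint_and_empty(self):
        a = np.zeros((10, 10), dtype=bool)
        a[2:5, 2:5] = True
        b = np.zeros_like(a)
        b[6:9, 6:9] = True
        assert motion_score(a, a) == 0.0
        assert motion_score(a, b) == 1.0
        assert motion_score(np.zeros_like(a), np.zeros_like(a)) == 0.0

    def test_one_pixel_shift_matches_set_arithmetic(self):
        a = np.zeros((100, 60), dtype=bool)
        a[10:90, 10:50] = True  # 40x80 rectangle
        b = np.roll(a, 1, axis=1)
        inter = (a & b).sum()
        union = (a | b).sum()
        assert motion_score(a, b) == pytest.approx(1 - inter / union)
        # exact counts: shifting by 1 removes/adds one 80-px column
        assert motion_score(a, b) == pytest.approx(1 - (40 - 1) * 80 / ((40 + 1) * 80))


class TestTransitionFrames:
    def test_fall_timing_stand_until_263_lie_at_283(self):
        history = [FrameState(i, STAND, 1.0, 0.0) for i in range(264)]
        history += [FrameState(i, BEND, 1.0, 0.5) for i in range(264, 283)]
        history += [FrameState(283, LIE, 1.0, 0.0)]
        assert transition_frames(history, 283) == 20.0

    def test_slow_lying_exceeds_eighty(self):
        history = [FrameState(0, STAND, 1.0, 0.0)]
        history += [FrameState(i, BEND, 1.0, 0.2) for i in range(1, 85)]
        history += [FrameState(85, LIE, 1.0, 0.0)]
        assert transition_frames(history, 85) == 85.0

    def test_sentinel_when_never_upright(self):
        history = [FrameState(i, LIE, 1.0, 0.0) for i in range(10)]
        assert transition_frames(history, 9) == math.inf


def scripted_stream(
    abnormal=True,
    on_floor=True,
    fast_transition=True,
    inactive=True,
    n_stand=5,
    n_tail=40,
):
    """Build a stream where each of the four rules is independently satisfied
    or violated; used as the truth-table oracle."""
    coverage = 0.95 if on_floor else 0.5
    posture = LIE if abnormal else SIT
    stream = [FrameState(i, STAND, 1.0, 0.2) for i in range(n_stand)]
    t = n_stand
    gap = 10 if fast_transition else 60
    for _ in range(gap):
        stream.append(FrameState(t, BEND if abnormal else STAND, coverage, 0.4))
        t += 1
    tail_motion = 0.01 if inactive else 0.2
    for _ in range(n_tail):
        stream.append(FrameState(t, posture, coverage, tail_motion))
        t += 1
    return stream


class TestDetectFall:
    def test_classic_fall_is_confirmed(self):
        # lie with coverage 0.9, 11-frame transition, then 30 motionless frames
        stream = [FrameState(i, STAND, 1.0, 0.2) for i in range(20)]
        stream += [FrameState(20 + j, BEND, 0.9, 0.4) for j in range(10)]
        stream += [FrameState(30 + j, LIE, 0.9, 0.01) for j in range(30)]
        decisions = detect_fall(stream)
        falls = [d for d in decisions if d.verdict == "fall"]
        assert len(falls) == 1
        assert falls[0].transition_frames == 11.0
        assert falls[0].rule_abnormal and falls[0].rule_floor
        assert falls[0].rule_transition and falls[0].rule_inactive

    def test_bend_off_floor_is_not_a_fall(self):
        stream = [FrameState(i, STAND, 1.0, 0.2) for i in range(5)]
        stream += [FrameState(5 + j, BEND, 0.5, 0.01) for j in range(40)]
        assert all(d.verdict == "no_fall" for d in detect_fall(stream))

    def test_slow_lying_is_not_a_fall(self):
        stream = [FrameState(0, STAND, 1.0, 0.2)]
        stream += [FrameState(1 + j, BEND, 0.95, 0.3) for j in range(85)]
        stream += [FrameState(86 + j, LIE, 0.95, 0.01) for j in range(40)]
        assert all(d.verdict == "no_fall" for d in detect_fall(stream))

    def test_never_upright_person_never_alarms(self):
        stream = [FrameState(j, LIE, 0.95, 0.01) for j in range(60)]
        assert all(d.verdict == "no_fall" for d in detect_fall(stream))

    @pytest.mark.parametrize(
        "abnormal,on_floor,fast,inactive",
        list(itertools.product([True, False], repeat=4)),
    )
    def test_truth_table_fall_iff_all_four_conditions(self, abnormal, on_floor, fast, inactive):
        stream = scripted_stream(abnormal, on_floor, fast, inactive)
        decisions = detect_fall(stream)
        n_falls = sum(d.verdict == "fall" for d in decisions)
        assert n_falls == (1 if (abnormal and on_floor and fast and inactive) else 0)
        for d in decisions:
            assert (d.verdict == "fall") == (
                d.rule_abnormal and d.rule_floor and d.rule_transition and d.rule_inactive
            )

    def test_exactly_one_event_per_episode(self):
        stream = scripted_stream(n_tail=120)  # conditions persist long after alarm
        assert sum(d.verdict == "fall" for d in detect_fall(stream)) == 1

    def test_rearms_after_recovery(self):
        stream = scripted_stream(n_tail=40)
        t = stream[-1].frame_index + 1
        stream += [FrameState(t + i, STAND, 1.0, 0.2) for i in range(10)]
        t += 10
        stream += [FrameState(t + j, LIE, 0.95, 0.01) for j in range(40)]
        assert sum(d.verdict == "fall" for d in detect_fall(stream)) == 2

    def test_verdict_monotone_in_thresholds(self):
        stream = scripted_stream()
        base = detect_fall(stream, params=FallRuleParams())
        assert any(d.verdict == "fall" for d in base)
        for params in (
            FallRuleParams(coverage_threshold=0.5),
            FallRuleParams(transition_max=60),
        ):
            relaxed = detect_fall(stream, params=params)
            assert any(d.verdict == "fall" for d in relaxed)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="empty stream"):
            detect_fall([])

    def test_abnormal_set_is_lie_and_bend(self):
        from fallwatch.classifier import ABNORMAL_POSTURES

        assert ABNORMAL_POSTURES == {POSTURE_CODES["lie"], POSTURE_CODES["bend"]}
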