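"""Tests of behaviour classification, free-fall estimation and activity scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from larvatrack import (
    BehaviorSegment,
    MotionModel,
    Track,
    classify_track,
    estimate_freefall_speed,
    generate_motility_frames,
    split_light_sequences,
    summarize_motility,
    swimming_activity_frequency,
)


def truth_track(truth, larva=0, track_id=0):
    """Build a track directly from continuous ground-truth positions."""
    n = len(truth.timestamps)
    return Track(track_id=track_id, frames=np.arange(n), times=truth.timestamps,
                 x_mm=truth.x_mm[larva], y_mm=truth.y_mm[larva],
                 area_mm2=np.zeros(n))


def seg(label, start, end, track_id=0, vy=0.0):
    return BehaviorSegment(track_id=track_id, start_s=start, end_s=end,
                           label=label, mean_vy_cm_s=vy)


class TestLightSequences:
    def test_ninety_minutes_gives_six_alternating_sequences(self):
        seqs = split_light_sequences(90 * 60, 15 * 60)
        assert len(seqs) == 6
        assert [light for _, light in seqs] == ["CWL", "IR"] * 3
        assert seqs[0][0] == (0.0, 900.0)
        assert seqs[-1][0] == (4500.0, 5400.0)

    def test_single_sequence(self):
        assert len(split_light_sequences(900, 900)) == 1

    def test_non_multiple_duration_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            split_light_sequences(90 * 60, 20 * 60)

    def test_first_label_configurable(self):
        seqs = split_light_sequences(3600, 900, first_label="IR")
        assert [light for _, light in seqs] == ["IR", "CWL", "IR", "CWL"]


class TestClassifyTrack:
    def test_settled_larva_single_settled_segment(self, quiet_scene):
        scene = quiet_scene(duration_s=10.0)
        _, truth = generate_motility_frames(
            scene, [MotionModel(kind="settled", initial_xy_mm=(4.0, 11.5))])
        segs = classify_track(truth_track(truth), container_height_mm=scene.height_mm)
        assert len(segs) == 1
        assert segs[0].label == "settled"
        assert segs[0].start_s == 0.0
        assert segs[0].end_s == pytest.approx(10.0)

    def test_midcolumn_sinker_is_free_fall(self, quiet_scene):
        scene = quiet_scene(height_px=300, duration_s=10.0)
        _, truth = generate_motility_frames(
            scene, [MotionModel(kind="sinker", fall_speed_mean=0.15,
                                initial_xy_mm=(4.0, 3.0))])
        segs = classify_track(truth_track(truth), container_height_mm=scene.height_mm)
        assert len(segs) == 1
        assert segs[0].label == "free_fall"
        assert segs[0].mean_vy_cm_s == pytest.approx(0.15, rel=1e-6)

    def test_crawler_labelled_crawling(self, quiet_scene):
        scene = quiet_scene(duration_s=10.0)
        _, truth = generate_motility_frames(
            scene, [MotionModel(kind="crawler", swim_speed=0.2,
                                direction_persistence=1.0)])
        segs = classify_track(truth_track(truth), container_height_mm=scene.height_mm)
        assert {s.label for s in segs} == {"crawling"}

    def test_random_walk_swimmer_mostly_swimming(self, quiet_scene):
        scene = quiet_scene(width_px=400, height_px=400, duration_s=30.0,
                            fps=25.0, seed=11)
        _, truth = generate_motility_frames(
            scene, [MotionModel(kind="swimmer", swim_speed=0.3,
                                direction_persistence=0.8,
                                initial_xy_mm=(20.0, 15.0))])
        segs = classify_track(truth_track(truth), container_height_mm=scene.height_mm)
        total = sum(s.duration_s for s in segs)
        swim = sum(s.duration_s for s in segs if s.label == "swimming")
        assert swim / total >= 0.95

    def test_segments_partition_tracked_time(self, quiet_scene):
        scene = quiet_scene(height_px=300, duration_s=12.0, seed=3)
        larva = MotionModel(kind="sinker", fall_speed_mean=0.3,
                            initial_xy_mm=(4.0, 2.0),
                            bout_schedule=((4.0, 8.0, "swimmer"),),
                            swim_speed=0.3)
        _, truth = generate_motility_frames(scene, [larva])
        segs = classify_track(truth_track(truth), container_height_mm=scene.height_mm)
        dt = float(np.diff(truth.timestamps).mean())
        assert segs[0].start_s == truth.timestamps[0]
        assert segs[-1].end_s == pytest.approx(truth.timestamps[-1] + dt)
        for a, b in zip(segs, segs[1:]):
            assert b.start_s == pytest.approx(a.end_s)

    def test_too_short_track_rejected(self):
        tr = Track(track_id=0, frames=np.array([0]), times=np.array([0.0]),
                   x_mm=np.array([1.0]), y_mm=np.array([1.0]),
                   area_mm2=np.array([0.1]))
        with pytest.raises(ValueError):
            classify_track(tr, container_height_mm=100.0)


class TestFreeFall:
    @staticmethod
    def uniform_descent_track(speed_cm_s, container_mm=200.0, fps=25.0,
                              duration=150.0):
        n = int(duration * fps)
        t = np.arange(n) / fps
        y = 10.0 + speed_cm_s * 10.0 * t
        keep = y < container_mm - 5.0
        return Track(track_id=0, frames=np.arange(n)[keep], times=t[keep],
                     x_mm=np.full(keep.sum(), 20.0), y_mm=y[keep],
                     area_mm2=np.zeros(keep.sum()))

    def test_uniform_descent_recovered_exactly(self):
        tr = self.uniform_descent_track(0.1)
        est = estimate_freefall_speed([tr], container_height_cm=20.0)
        assert len(est) == 1
        assert est[0].speed_cm_s == pytest.approx(0.1, rel=1e-9)
        assert est[0].roi_cm == (7.5, 12.5)

    def test_swimmer_only_stack_gives_no_estimates(self, quiet_scene):
        scene = quiet_scene(width_px=300, height_px=300, duration_s=20.0,
                            fps=25.0, seed=4)
        _, truth = generate_motility_frames(
            scene, [MotionModel(kind="swimmer", swim_speed=0.3,
                                initial_xy_mm=(15.0, 15.0))])
        est = estimate_freefall_speed([truth_track(truth)],
                                      container_height_cm=scene.height_mm / 10,
                                      roi_height_cm=2.0)
        assert est == []

    def test_roi_taller_than_container_rejected(self):
        tr = self.uniform_descent_track(0.1)
        with pytest.raises(ValueError):
            estimate_freefall_speed([tr], container_height_cm=4.0)

    def test_temperature_grouping(self):
        tr = self.uniform_descent_track(0.1)
        est_low = estimate_freefall_speed([tr], container_height_cm=20.0,
                                          temperature_c=20.0)
        est_high = estimate_freefall_speed([tr], container_height_cm=20.0,
                                           temperature_c=22.5)
        assert est_low[0].temp_group == "19-21C"
        assert est_high[0].temp_group == "21-23C"


class TestActivityFrequency:
    def test_all_larvae_swimming_entire_sequence_is_100(self):
        segments = [seg("swimming", 0.0, 900.0, track_id=i) for i in range(10)]
        assert swimming_activity_frequency(segments, 10, (0.0, 900.0)) == 100.0

    def test_no_swimming_is_0(self):
        segments = [seg("settled", 0.0, 900.0, track_id=i) for i in range(10)]
        assert swimming_activity_frequency(segments, 10, (0.0, 900.0)) == 0.0

    def test_half_coverage_is_50(self):
        # 10 larvae, 900 s sequence, 4500 larva-seconds of swimming
        segments = [seg("swimming", 0.0, 450.0, track_id=i) for i in range(10)]
        assert swimming_activity_frequency(segments, 10, (0.0, 900.0)) == 50.0

    def test_overlap_clipped_to_interval(self):
        segments = [seg("swimming", 800.0, 1000.0)]
        f = swimming_activity_frequency(segments, 1, (0.0, 900.0))
        assert f == pytest.approx(100.0 * 100.0 / 900.0)

    def test_zero_larvae_rejected(self):
        with pytest.raises(ValueError):
            swimming_activity_frequency([], 0, (0.0, 900.0))

    @given(
        st.lists(
            st.tuples(st.integers(0, 4), st.floats(0, 5400), st.floats(1, 900),
                      st.booleans()),
            max_size=20,
        )
    )
    def test_frequency_bounded(self, raw):
        """F stays within [0, 100] for any non-overlapping per-track bouts."""
        by_track = {}
        segments = []
        for tid, start, dur, swims in raw:
            t0 = max(by_track.get(tid, 0.0), start)
            t1 = t0 + dur
            by_track[tid] = t1
            segments.append(seg("swimming" if swims else "settled", t0, t1, tid))
        f = swimming_activity_frequency(segments, 5, (0.0, 5400.0))
        assert 0.0 <= f <= 100.0


class TestSummarize:
    @staticmethod
    def freq_table(freqs, replicate=1):
        lights = ["CWL", "IR"] * 3
        return pd.DataFrame(
            {
                "replicate": replicate,
                "sequence_index": range(1, 7),
                "light": lights,
                "frequency_pct": freqs,
            }
        )

    def test_identical_frequencies_pool_identically(self):
        per_seq, pooled = summarize_motility(self.freq_table([42.0] * 6))
        assert per_seq["stimulation_window"].tolist() == [True, True] + [False] * 4
        assert set(pooled["mean_frequency_pct"]) == {42.0}

    def test_pooling_uses_only_post_stimulation_sequences(self):
        _, pooled = summarize_motility(self.freq_table([10, 20, 30, 40, 50, 60]))
        cwl = pooled.loc[pooled["light"] == "CWL", "mean_frequency_pct"].iloc[0]
        ir = pooled.loc[pooled["light"] == "IR", "mean_frequency_pct"].iloc[0]
        assert cwl == pytest.approx((30 + 50) / 2)
        assert ir == pytest.approx((40 + 60) / 2)

    def test_missing_sequences_lower_n(self):
        table = self.freq_table([10, 20, 30, 40, 50, 60]).iloc[:5]  # IR3 missing
        _, pooled = summarize_motility(table)
        assert pooled.loc[pooled["light"] == "IR", "n"].iloc[0] == 1
        assert pooled.loc[pooled["light"] == "CWL", "n"].iloc[0] == 2

    def test_two_replicates_pool_together(self):
        table = pd.concat([self.freq_table([0, 0, 30, 40, 50, 60], replicate=1),
                           self.freq_table([0, 0, 50, 60, 70, 80], replicate=2)])
        _, pooled = summarize_motility(table)
        cwl = pooled.loc[pooled["light"] == "CWL"].iloc[0]
        assert cwl["mean_frequency_pct"] == pytest.approx((30 + 50 + 50 + 70) / 4)
        assert cwl["n"] == 4

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            summarize_motility(pd.DataFrame({"frequency_pct": [1.0]}))
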