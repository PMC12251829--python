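"""Threshold-and-merge post-processing tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afdet.evaluate import duration_metrics
from afdet.postprocess import (EpisodeSegment, MergeConfig, labels_to_segments,
                               merge_episodes, merge_segments,
                               probs_to_episodes, sweep, threshold_windows)


class TestThreshold:
    def test_threshold_is_inclusive(self):
        cfg = MergeConfig(prob_threshold=0.75)
        out = threshold_windows([0.75, 0.7499, 0.76, 0.0], cfg)
        assert out.tolist() == [1, 0, 1, 0]

    def test_all_zero_probabilities_give_all_nsr(self):
        assert threshold_windows(np.zeros(10)).sum() == 0

    def test_strict_mode_excludes_boundary(self):
        cfg = MergeConfig(prob_threshold=0.7, threshold_inclusive=False)
        assert threshold_windows([0.7, 0.71], cfg).tolist() == [0, 1]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            threshold_windows([1.2])


class TestMerge:
    def test_six_window_worked_example(self):
        """[A,A,N,N,N,A] with a 30 s gap merges into one 60 s episode."""
        segs = merge_episodes([1, 1, 0, 0, 0, 1], MergeConfig(t_gap_s=30))
        assert len(segs) == 1
        assert (segs[0].start_s, segs[0].end_s) == (0.0, 60.0)
        assert segs[0].duration_s == 60.0

    def test_three_window_worked_example(self):
        """A(0-10), N(10-20), A(20-30) merges into a single 30 s episode."""
        segs = merge_episodes([1, 0, 1], MergeConfig(t_gap_s=30))
        assert len(segs) == 1
        assert segs[0].duration_s == 30.0

    def test_gap_strictly_larger_than_threshold_not_bridged(self):
        segs = merge_episodes([1, 0, 0, 0, 0, 1], MergeConfig(t_gap_s=30))
        assert len(segs) == 2
        segs = merge_episodes([1, 0, 0, 0, 1], MergeConfig(t_gap_s=30))
        assert len(segs) == 1  # 30 s gap, inclusive

    def test_no_afib_windows_no_segments(self):
        assert merge_episodes([0, 0, 0, 0]) == []
        assert merge_episodes([]) == []

    def test_merge_idempotent(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            labels = rng.integers(0, 2, size=30)
            once = merge_episodes(labels, MergeConfig(t_gap_s=40))
            again = merge_segments(once, 40.0)
            assert again == once

    def test_min_episode_filter(self):
        cfg = MergeConfig(t_gap_s=0, min_episode_s=30)
        segs = merge_episodes([1, 0, 1, 1, 1], cfg)
        assert [s.duration_s for s in segs] == [30.0]

    @given(st.lists(st.integers(0, 1), max_size=40),
           st.sampled_from([0.0, 10.0, 30.0, 40.0, 60.0]))
    @settings(max_examples=200, deadline=None)
    def test_merge_covers_every_afib_window_and_respects_gaps(self, labels, gap):
        segs = merge_episodes(labels, MergeConfig(t_gap_s=gap))
        # disjoint and sorted
        for a, b in zip(segs, segs[1:]):
            assert a.end_s < b.start_s
            assert b.start_s - a.end_s > gap  # unbridged gaps exceed t_gap
        # every AFib window covered by exactly one segment
        for i, lab in enumerate(labels):
            covered = [s for s in segs
                       if s.start_s <= i * 10.0 and (i + 1) * 10.0 <= s.end_s]
            assert len(covered) == (1 if lab else len(covered) or 0)
            if lab:
                assert len(covered) == 1

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_monotonicity_in_gap(self, labels):
        """Segments for gap g nest inside segments for g' >= g; total duration
        is non-decreasing; covered AFib-window count is conserved."""
        durations = []
        prev_segs = None
        for gap in (0.0, 10.0, 30.0, 50.0):
            segs = merge_episodes(labels, MergeConfig(t_gap_s=gap))
            durations.append(sum(s.duration_s for s in segs))
            if prev_segs is not None:
                for small in prev_segs:
                    assert any(big.start_s <= small.start_s
                               and small.end_s <= big.end_s for big in segs)
            prev_segs = segs
        assert durations == sorted(durations)
        n_afib = sum(labels)
        segs0 = merge_episodes(labels, MergeConfig(t_gap_s=0.0))
        assert sum(s.duration_s for s in segs0) == 10.0 * n_afib


class TestSweep:
    def test_single_cell_grid_equals_direct_evaluation(self):
        probs = np.array([0.9, 0.2, 0.8, 0.1])
        ref = [EpisodeSegment(0, 10), EpisodeSegment(20, 30)]
        grid = sweep(probs, ref, [0.75], [30.0])
        direct = duration_metrics(
            ref, probs_to_episodes(probs, MergeConfig(t_gap_s=30.0)))
        assert grid[(0.75, 30.0)] == direct

    def test_sensitivity_non_increasing_in_threshold(self):
        rng = np.random.default_rng(5)
        probs = rng.random(60)
        ref = [EpisodeSegment(0, 600)]
        ths = [0.1, 0.3, 0.5, 0.7, 0.9]
        grid = sweep(probs, ref, ths, [40.0])
        ses = [grid[(t, 40.0)].sensitivity for t in ths]
        assert all(a >= b - 1e-12 for a, b in zip(ses, ses[1:]))

    def test_merged_duration_non_decreasing_in_gap(self):
        rng = np.random.default_rng(6)
        probs = rng.random(60)
        gaps = [0.0, 20.0, 40.0, 60.0]
        durs = []
        for g in gaps:
            segs = probs_to_episodes(probs, MergeConfig(t_gap_s=g))
            durs.append(sum(s.duration_s for s in segs))
        assert durs == sorted(durs)
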