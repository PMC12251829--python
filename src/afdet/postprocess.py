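"""Threshold window posteriors and merge them into rhythm episodes.

A window is called AFib when p_AFib >= 0.75 (inclusive; both the value and
the strictness are configurable). Consecutive AFib windows form runs; any two
runs separated by at most ``t_gap_s`` seconds of non-AFib are merged into a
single episode spanning from the start of the first to the end of the last
window — the gap itself becomes part of the episode. With the worked
six-window sequence [AFib, AFib, NSR, NSR, NSR, AFib] and a 30 s gap
threshold this yields one 60 s episode; [AFib, NSR, AFib] yields one 30 s
episode. No minimum-duration rule is applied by default (the 30 s clinical
reporting rule is available as ``min_episode_s``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import AFIB

__all__ = ["MergeConfig", "EpisodeSegment", "threshold_windows",
           "labels_to_segments", "merge_segments", "merge_episodes", "sweep"]


@dataclass(frozen=True)
class MergeConfig:
    prob_threshold: float = 0.75
    threshold_inclusive: bool = True
    t_gap_s: float = 40.0
    window_len_s: float = 10.0
    min_episode_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must lie in (0, 1)")
        if self.t_gap_s < 0 or self.min_episode_s < 0:
            raise ValueError("t_gap_s and min_episode_s must be >= 0")


@dataclass(frozen=True)
class EpisodeSegment:
    """A merged predicted (or reference) AFib interval [start_s, end_s)."""

    start_s: float
    end_s: float
    label: str = AFIB

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"empty segment [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def threshold_windows(probs: np.ndarray,
                      cfg: MergeConfig = MergeConfig()) -> np.ndarray:
    """Binary AFib labels from per-window p_AFib (1 iff p >= threshold)."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if cfg.threshold_inclusive:
        return (probs >= cfg.prob_threshold).astype(np.int8)
    return (probs > cfg.prob_threshold).astype(np.int8)


def labels_to_segments(labels: Sequence[int], window_len_s: float = 10.0,
                       start_s: float = 0.0) -> list[EpisodeSegment]:
    """Turn consecutive window labels into maximal runs of AFib windows."""
    labels = np.asarray(labels)
    out = []
    run_start = None
    for i, lab in enumerate(labels):
        if lab and run_start is None:
            run_start = i
        elif not lab and run_start is not None:
            out.append(EpisodeSegment(start_s + run_start * window_len_s,
                                      start_s + i * window_len_s))
            run_start = None
    if run_start is not None:
        out.append(EpisodeSegment(start_s + run_start * window_len_s,
                                  start_s + len(labels) * window_len_s))
    return out


def merge_segments(segments: Sequence[EpisodeSegment], t_gap_s: float,
                   min_episode_s: float = 0.0) -> list[EpisodeSegment]:
    """Gap-closing merge: bridge gaps of at most ``t_gap_s`` seconds.

    Idempotent, and monotone in ``t_gap_s``: every output segment for gap g
    is contained in some output segment for any gap g' >= g.
    """
    if t_gap_s < 0:
        raise ValueError("t_gap_s must be >= 0")
    segs = sorted(segments, key=lambda s: s.start_s)
    merged: list[EpisodeSegment] = []
    for seg in segs:
        if merged and seg.start_s - merged[-1].end_s <= t_gap_s:
            last = merged[-1]
            merged[-1] = EpisodeSegment(last.start_s,
                                        max(last.end_s, seg.end_s), last.label)
        else:
            merged.append(seg)
    if min_episode_s > 0:
        merged = [s for s in merged if s.duration_s >= min_episode_s]
    return merged


def merge_episodes(labels: Sequence[int],
                   cfg: MergeConfig = MergeConfig()) -> list[EpisodeSegment]:
    """Binary window-label sequence -> merged episode segments."""
    runs = labels_to_segments(labels, cfg.window_len_s)
    return merge_segments(runs, cfg.t_gap_s, cfg.min_episode_s)


def probs_to_episodes(probs: np.ndarray,
                      cfg: MergeConfig = MergeConfig()) -> list[EpisodeSegment]:
    """Full post-processing chain: threshold then gap-closing merge."""
    return merge_episodes(threshold_windows(probs, cfg), cfg)


def sweep(probs: np.ndarray, reference, thresholds: Sequence[float],
          gaps: Sequence[float], cfg: MergeConfig = MergeConfig()):
    """Evaluate every (threshold, gap) pair against reference episodes.

    Returns a dict mapping (threshold, t_gap_s) to an EvalResult; used for
    threshold/merging-gap trade-off curves.
    """
    from .evaluate import duration_metrics

    grid = {}
    for th in thresholds:
        for gap in gaps:
            c = replace(cfg, prob_threshold=th, t_gap_s=gap)
            grid[(th, gap)] = duration_metrics(reference, probs_to_episodes(probs, c))
    return grid
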