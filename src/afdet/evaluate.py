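"""Duration-overlap evaluation of AFib episode predictions.

For reference regions R = {r_i} and predicted regions P = {p_j} (each a
half-open interval in seconds),

    Overlap(r_i, p_j) = max(0, min(r_i.end, p_j.end) - max(r_i.start, p_j.start))
    TotalOverlap      = sum_i sum_j Overlap(r_i, p_j)
    Sensitivity       = TotalOverlap / |R|      (reference AFib duration)
    Precision         = TotalOverlap / |P|      (predicted AFib duration)
    F1                = 2 Se Pr / (Se + Pr)

Segments within one set must be disjoint (the double sum would otherwise
double-count; merge first). Pooled ("Overall") metrics are computed from the
summed durations across records, not by averaging per-record ratios. Records
with neither reference nor predicted AFib carry no duration information and
are excluded from pooling; a missing denominator makes the corresponding
metric NaN for that record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["EvalResult", "interval_overlap", "total_overlap",
           "duration_metrics", "pool_records", "format_hms", "format_report"]

Interval = tuple[float, float]


def _as_pairs(segments) -> list[Interval]:
    out = []
    for s in segments:
        if hasattr(s, "start_s"):
            out.append((float(s.start_s), float(s.end_s)))
        else:
            a, b = s
            out.append((float(a), float(b)))
    return out


@dataclass(frozen=True)
class EvalResult:
    sensitivity: float
    precision: float
    f1: float
    ref_duration_s: float
    pred_duration_s: float
    overlap_duration_s: float
    record_id: str | None = None


def interval_overlap(r: Interval, p: Interval) -> float:
    """Overlap in seconds between two intervals (0 when disjoint)."""
    (ra, rb), (pa, pb) = _as_pairs([r, p])
    return max(0.0, min(rb, pb) - max(ra, pa))


def _check_disjoint(pairs: list[Interval], name: str) -> None:
    pairs = sorted(pairs)
    for (a0, b0), (a1, _) in zip(pairs, pairs[1:]):
        if a1 < b0 - 1e-12:
            raise ValueError(
                f"{name} contains overlapping segments "
                f"[{a0}, {b0}) and starting {a1}; merge before evaluating")


def total_overlap(R, P) -> float:
    """TotalOverlap = sum over all pairs; equals the measure of (∪R) ∩ (∪P).

    Both sets must be internally disjoint.
    """
    Rp, Pp = _as_pairs(R), _as_pairs(P)
    _check_disjoint(Rp, "reference set")
    _check_disjoint(Pp, "predicted set")
    if not Rp or not Pp:
        return 0.0
    ra = np.array([a for a, _ in Rp])
    rb = np.array([b for _, b in Rp])
    pa = np.array([a for a, _ in Pp])
    pb = np.array([b for _, b in Pp])
    ov = np.maximum(0.0, np.minimum(rb[:, None], pb[None, :])
                    - np.maximum(ra[:, None], pa[None, :]))
    return float(ov.sum())


def sweepline_overlap(R, P) -> float:
    """Independent sweep-line computation of the R/P intersection measure."""
    events = []
    for a, b in _as_pairs(R):
        events += [(a, 0, 1), (b, 0, -1)]
    for a, b in _as_pairs(P):
        events += [(a, 1, 1), (b, 1, -1)]
    events.sort()
    depth = [0, 0]
    total, prev = 0.0, None
    for t, which, d in events:
        if prev is not None and depth[0] > 0 and depth[1] > 0:
            total += t - prev
        depth[which] += d
        prev = t
    return total


def _metrics_from_durations(ref: float, pred: float, ov: float,
                            record_id: str | None = None) -> EvalResult:
    se = ov / ref if ref > 0 else math.nan
    pr = ov / pred if pred > 0 else math.nan
    if ref > 0 and pred == 0:
        se, pr = 0.0, math.nan
    if ref == 0 and pred > 0:
        se, pr = math.nan, 0.0
    if not math.isnan(se) and not math.isnan(pr) and (se + pr) > 0:
        f1 = 2 * se * pr / (se + pr)
    elif se == 0.0 or pr == 0.0:
        f1 = 0.0
    else:
        f1 = math.nan
    return EvalResult(se, pr, f1, ref, pred, ov, record_id)


def duration_metrics(R, P, record_id: str | None = None) -> EvalResult:
    """Sensitivity / precision / F1 from duration overlap of two segment sets."""
    ov = total_overlap(R, P)
    ref = sum(b - a for a, b in _as_pairs(R))
    pred = sum(b - a for a, b in _as_pairs(P))
    return _metrics_from_durations(ref, pred, ov, record_id)


def pool_records(per_record: Sequence[EvalResult]) -> EvalResult:
    """'Overall' metrics from durations summed across records.

    Records with zero reference *and* zero predicted duration contribute
    nothing and are skipped (they are omitted from report tables as well).
    """
    if not per_record:
        raise ValueError("no records to pool")
    used = [r for r in per_record
            if r.ref_duration_s > 0 or r.pred_duration_s > 0]
    if not used:
        return _metrics_from_durations(0.0, 0.0, 0.0, "Overall")
    ref = sum(r.ref_duration_s for r in used)
    pred = sum(r.pred_duration_s for r in used)
    ov = sum(r.overlap_duration_s for r in used)
    return _metrics_from_durations(ref, pred, ov, "Overall")


def format_hms(seconds: float) -> str:
    """Whole-second HH:MM:SS (hours may exceed 99 for pooled durations)."""
    s = int(round(seconds))
    return f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}"


def _fmt(x: float) -> str:
    return "--" if math.isnan(x) else f"{x:.3f}"


def format_report(per_record: Sequence[EvalResult],
                  csv: bool = False) -> str:
    """Per-record + Overall table: Record, Se, Pr, F1, Ref/Pred/Overlap durations.

    Records without any true or predicted AFib are omitted, matching how
    duration tables are conventionally reported.
    """
    rows = [r for r in per_record
            if r.ref_duration_s > 0 or r.pred_duration_s > 0]
    overall = pool_records(per_record)
    header = ["Record", "Sensitivity", "Precision", "F1",
              "Ref duration", "Pred duration", "Overlap duration"]
    body = [[r.record_id or "?", _fmt(r.sensitivity), _fmt(r.precision),
             _fmt(r.f1), format_hms(r.ref_duration_s),
             format_hms(r.pred_duration_s), format_hms(r.overlap_duration_s)]
            for r in rows]
    body.append(["Overall", _fmt(overall.sensitivity), _fmt(overall.precision),
                 _fmt(overall.f1), format_hms(overall.ref_duration_s),
                 format_hms(overall.pred_duration_s),
                 format_hms(overall.overlap_duration_s)])
    if csv:
        return "\n".join(",".join(row) for row in [header] + body)
    widths = [max(len(r[i]) for r in [header] + body) for i in range(len(header))]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    lines += ["  ".join(c.ljust(w) for c, w in zip(row, widths)) for row in body]
    return "\n".join(lines)
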