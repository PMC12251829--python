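"""Duration-overlap metric tests, including brute-force oracles."""

import math

import numpy as np
import pytest

from afdet.evaluate import (EvalResult, duration_metrics, format_hms,
                            format_report, interval_overlap, pool_records,
                            sweepline_overlap, total_overlap)


def rasterized_overlap(R, P, span, cell=0.01):
    """Independent oracle: discretize both sets on a fine grid and intersect."""
    n = int(round(span / cell))
    grid_r = np.zeros(n, dtype=bool)
    grid_p = np.zeros(n, dtype=bool)
    for a, b in R:
        grid_r[int(round(a / cell)):int(round(b / cell))] = True
    for a, b in P:
        grid_p[int(round(a / cell)):int(round(b / cell))] = True
    return (grid_r & grid_p).sum() * cell


def random_disjoint_segments(rng, span=100.0, max_n=6):
    """Random internally-disjoint segment set on a 0.01 s lattice."""
    k = rng.integers(0, max_n + 1)
    cuts = np.sort(rng.integers(0, int(span * 100), size=2 * k)) / 100.0
    segs = [(cuts[2 * i], cuts[2 * i + 1]) for i in range(k)
            if cuts[2 * i + 1] > cuts[2 * i]]
    # enforce strict disjointness (sorting can produce touching segments, fine)
    out = []
    for a, b in segs:
        if out and a < out[-1][1]:
            continue
        out.append((a, b))
    return out


@pytest.mark.parametrize("r, p, expected", [
    ((0, 10), (5, 15), 5.0),
    ((0, 10), (20, 30), 0.0),
    ((0, 100), (40, 60), 20.0),
    ((0, 10), (10, 20), 0.0),      # touching half-open intervals are disjoint
])
def test_interval_overlap_formula(r, p, expected):
    assert interval_overlap(r, p) == expected
    assert interval_overlap(p, r) == expected


def test_total_overlap_identical_and_disjoint_sets():
    R = [(0.0, 10.0), (20.0, 35.0)]
    assert total_overlap(R, R) == 25.0
    assert total_overlap(R, [(10.0, 20.0), (40.0, 50.0)]) == 0.0


def test_total_overlap_rejects_overlapping_input():
    with pytest.raises(ValueError, match="merge"):
        total_overlap([(0, 10), (5, 20)], [(0, 1)])


def test_total_overlap_agrees_with_rasterization_and_sweepline():
    """Double-sum == sweep-line exactly; == 0.01 s rasterization within
    one grid cell per boundary, over many random disjoint segment pairs."""
    rng = np.random.default_rng(42)
    for _ in range(300):
        R = random_disjoint_segments(rng)
        P = random_disjoint_segments(rng)
        ds = total_overlap(R, P)
        sw = sweepline_overlap(R, P)
        assert ds == pytest.approx(sw, abs=1e-9)
        ras = rasterized_overlap(R, P, span=100.0)
        n_bounds = 2 * (len(R) + len(P))
        assert abs(ds - ras) <= 0.01 * n_bounds + 1e-9


def test_total_overlap_symmetry_and_bound():
    rng = np.random.default_rng(7)
    for _ in range(100):
        R = random_disjoint_segments(rng)
        P = random_disjoint_segments(rng)
        ov = total_overlap(R, P)
        assert ov == pytest.approx(total_overlap(P, R))
        assert ov <= min(sum(b - a for a, b in R or [(0, 0)]),
                         sum(b - a for a, b in P or [(0, 0)])) + 1e-12


def test_duration_metrics_arithmetic():
    res = duration_metrics([(0, 100)], [(50, 150)])
    assert (res.sensitivity, res.precision, res.f1) == (0.5, 0.5, 0.5)
    perfect = duration_metrics([(0, 100)], [(0, 100)])
    assert (perfect.sensitivity, perfect.precision, perfect.f1) == (1, 1, 1)


def test_duration_metrics_degenerate_denominators():
    # reference but no prediction: Se = 0, Pr undefined
    res = duration_metrics([(0, 10)], [])
    assert res.sensitivity == 0.0 and math.isnan(res.precision)
    assert res.f1 == 0.0
    # prediction but no reference: Pr = 0, Se undefined
    res = duration_metrics([], [(0, 10)])
    assert res.precision == 0.0 and math.isnan(res.sensitivity)


def test_pool_records_sums_durations_not_ratios():
    a = duration_metrics([(0, 100)], [(10, 130)], "a")   # ref 100 pred 120 ov 90
    b = duration_metrics([(0, 50)], [(0, 40)], "b")      # ref 50 pred 40 ov 40
    pooled = pool_records([a, b])
    assert pooled.sensitivity == pytest.approx(130 / 150)
    assert pooled.precision == pytest.approx(130 / 160)
    # single record pools to itself; duplicated record leaves ratios unchanged
    assert pool_records([a]).sensitivity == a.sensitivity
    twice = pool_records([a, a])
    assert twice.sensitivity == pytest.approx(a.sensitivity)
    assert twice.precision == pytest.approx(a.precision)


def test_pooled_sensitivity_between_per_record_extremes():
    rng = np.random.default_rng(3)
    results = []
    for i in range(8):
        ref = rng.uniform(10, 100)
        ov = rng.uniform(0, ref)
        results.append(EvalResult(ov / ref, 1.0, 0.0, ref, ov, ov, str(i)))
    pooled = pool_records(results)
    ses = [r.sensitivity for r in results]
    assert min(ses) - 1e-12 <= pooled.sensitivity <= max(ses) + 1e-12


def test_format_hms_and_report_layout():
    assert format_hms(0) == "00:00:00"
    assert format_hms(3661) == "01:01:01"
    assert format_hms(95 * 3600 + 60 + 49) == "95:01:49"
    rows = [duration_metrics([(0, 100)], [(50, 150)], "r1"),
            duration_metrics([], [], "empty")]
    rep = format_report(rows)
    assert "Overall" in rep and "r1" in rep
    assert "empty" not in rep  # records without any AFib are omitted
    csv = format_report(rows, csv=True)
    assert csv.splitlines()[0].startswith("Record,Sensitivity,Precision")
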