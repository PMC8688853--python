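"""REI computation, event segmentation and patient summaries."""
from itertools import groupby

import numpy as np
import pandas as pd
import pytest

from amirei import (
    ExacerbationEvent,
    ValidationError,
    compute_rei,
    detect_events,
    exp_smooth,
    summarize_patient,
)
from amirei.rei import events_to_frame, in_event_mask


def brute_force_events(values, threshold):
    """Independent flag-then-group segmentation using itertools.groupby."""
    flags = [v < threshold for v in values]
    out, pos, prev_end = [], 0, None
    for flag, run in groupby(flags):
        n = sum(1 for _ in run)
        if flag:
            dist = None if prev_end is None else pos - prev_end
            out.append((pos, pos + n - 1, dist))
            prev_end = pos + n - 1
        pos += n
    return out


class TestComputeRei:
    def test_ratio(self):
        rei = compute_rei([55.0], [100.0])
        assert rei[0] == pytest.approx(0.55)
        assert rei[0] < 0.8

    def test_steady_state_is_one(self):
        np.testing.assert_allclose(compute_rei([80.0] * 5, [80.0] * 5), 1.0)

    def test_all_zero_history_convention(self):
        np.testing.assert_allclose(compute_rei([0.0, 0.0], [0.0, 0.0]), 1.0)

    def test_cap(self):
        assert compute_rei([100.0], [5.0], cap=10.0)[0] == 10.0

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValidationError):
            compute_rei([1.0, 2.0], [1.0])

    def test_zero_denominator_with_nonzero_numerator_rejected(self):
        with pytest.raises(ValidationError):
            compute_rei([5.0], [0.0])

    def test_denominator_zero_implies_numerator_zero_for_shared_history(self):
        # strictly positive smoothing weights: AMI-6 hits 0 only on all-zero input
        x = np.zeros(30)
        short, long_ = exp_smooth(x, 0.45), exp_smooth(x, 0.06)
        assert np.all(short[long_ == 0] == 0)
        np.testing.assert_allclose(compute_rei(short, long_), 1.0)


class TestDetectEvents:
    def test_run_length_example(self):
        rei = [1, 1, 0.7, 0.7, 0.9, 0.6, 1]
        events = detect_events(rei, 0.8)
        assert [(e.start_day, e.end_day, e.length) for e in events] == [
            (2, 3, 2),
            (5, 5, 1),
        ]
        assert events[0].dist_previous is None
        assert events[1].dist_previous == 2

    def test_no_events_when_all_at_or_above_threshold(self):
        assert detect_events([0.8, 1.0, 0.9], 0.8) == []

    def test_strict_inequality_at_threshold(self):
        rei = [1, 1, 0.7, 0.7, 0.9, 0.6, 1]
        events = detect_events(rei, 0.7)  # 0.7 days are out; only the 0.6 day is in
        assert [(e.start_day, e.end_day) for e in events] == [(5, 5)]

    def test_event_at_series_end_is_closed(self):
        events = detect_events([1.0, 0.5, 0.5], 0.8)
        assert [(e.start_day, e.end_day) for e in events] == [(1, 2)]

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            values = rng.uniform(0, 1.5, rng.integers(1, 60))
            tau = rng.uniform(0.2, 1.2)
            got = [(e.start_day, e.end_day, e.dist_previous) for e in detect_events(values, tau)]
            assert got == brute_force_events(values, tau)

    def test_conservation_of_event_lengths(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            values = rng.uniform(0, 1.5, 50)
            events = detect_events(values, 0.8)
            assert sum(e.length for e in events) == int((values < 0.8).sum())

    def test_threshold_monotonicity_of_in_event_days(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            values = rng.uniform(0, 1.5, 80)
            masks = {
                tau: in_event_mask(detect_events(values, tau), len(values))
                for tau in (0.7, 0.8, 0.9)
            }
            assert np.all(masks[0.7] <= masks[0.8])
            assert np.all(masks[0.8] <= masks[0.9])


def test_event_invariants():
    with pytest.raises(ValidationError):
        ExacerbationEvent(3, 2)
    with pytest.raises(ValidationError):
        ExacerbationEvent(3, 4, dist_previous=0)
    assert ExacerbationEvent(3, 4).length == 2


def _days(n, pid="P1", **cols):
    base = {
        "patient_id": pid,
        "date": pd.date_range("2023-01-02", periods=n),
        "treatment_day": np.arange(n),
        "mtbt_hours": np.full(n, 10.0),
        "ddd": np.full(n, np.nan),
        "peth_umol_l": np.full(n, np.nan),
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestSummarizePatient:
    def test_counting_example(self):
        events = detect_events([1, 1, 0.7, 0.7, 0.9, 0.6, 1], 0.8)
        s = summarize_patient(_days(7), None, events)
        assert s.percent_ee == pytest.approx(100 * 3 / 7)
        assert s.ee_count == 2
        assert s.mean_ee_length == pytest.approx(1.5)
        assert s.max_ee_length == 2
        assert s.mean_dist_previous == pytest.approx(2.0)

    def test_no_events(self):
        s = summarize_patient(_days(10), [100.0] * 10, [])
        assert s.percent_ee == 0.0 and s.ee_count == 0
        assert s.mean_ee_length is None and s.mean_dist_previous is None
        assert s.ami21_mean == 100.0

    def test_single_event_spanning_everything(self):
        s = summarize_patient(_days(5), None, [ExacerbationEvent(0, 4)])
        assert s.percent_ee == 100.0
        assert s.mean_dist_previous is None

    def test_min_event_length_filter(self):
        events = detect_events([1, 1, 0.7, 0.7, 0.9, 0.6, 1], 0.8)
        s = summarize_patient(_days(7), None, events, min_event_length=2)
        assert s.ee_count == 1 and s.percent_ee == pytest.approx(100 * 2 / 7)

    def test_zero_days_rejected(self):
        with pytest.raises(ValidationError):
            summarize_patient(_days(0), None, [])


def test_rei_level_invariance():
    """Scaling every raw score by c > 0 leaves the REI series unchanged."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = rng.uniform(0, 100, 120)
        base = compute_rei(exp_smooth(x, 0.45), exp_smooth(x, 0.06))
        for c in (0.5, 2.0, 10.0):
            scaled = compute_rei(exp_smooth(c * x, 0.45), exp_smooth(c * x, 0.06))
            np.testing.assert_allclose(scaled, base, atol=1e-9)


def test_events_to_frame_carries_dates():
    dates = list(pd.date_range("2023-01-02", periods=7))
    events = detect_events([1, 1, 0.7, 0.7, 0.9, 0.6, 1], 0.8)
    frame = events_to_frame(events, "P1", dates)
    assert list(frame["length_days"]) == [2, 1]
    assert frame["start_date"].iloc[0] == dates[2]
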