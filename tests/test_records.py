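"""Day aggregation: unit conversions, omission counting, MTBT attribution."""
import numpy as np
import pandas as pd
import pytest

from amirei import ValidationError, aggregate_days, brac_to_bac, compute_mtbt
from amirei.records import (
    TestRecord,
    level_of_quantification,
    read_day_table,
    write_day_table,
)

from conftest import make_log


@pytest.mark.parametrize(
    "brac,expected", [(0.025, 0.05), (0.0, 0.0), (1.0, 2.0), (0.4, 0.8)]
)
def test_brac_to_bac_factor(brac, expected):
    assert brac_to_bac(brac) == pytest.approx(expected)


def test_brac_to_bac_rejects_negative_and_handles_arrays():
    with pytest.raises(ValidationError):
        brac_to_bac(-0.01)
    np.testing.assert_allclose(brac_to_bac(np.array([0.1, 0.2])), [0.2, 0.4])


@pytest.mark.parametrize(
    "median,iqr,expected",
    [(0.006, 0.004, 0.046), (0.0, 0.0, 0.0), (0.01, 0.002, 0.03)],
)
def test_level_of_quantification(median, iqr, expected):
    assert level_of_quantification(median, iqr) == pytest.approx(expected)


def test_level_of_quantification_rejects_negative():
    with pytest.raises(ValidationError):
        level_of_quantification(-0.1, 0.0)


def test_test_record_invariants():
    t0 = pd.Timestamp("2023-01-02 08:00")
    with pytest.raises(ValidationError):
        TestRecord("P", t0, t0)  # empty window
    with pytest.raises(ValidationError):
        TestRecord("P", t0, t0 + pd.Timedelta("1h"), performed_at=t0 + pd.Timedelta("2h"), brac=0.0)
    with pytest.raises(ValidationError):
        TestRecord("P", t0, t0 + pd.Timedelta("1h"), performed_at=None, brac=0.1)
    rec = TestRecord("P", t0, t0 + pd.Timedelta("1h"), t0 + pd.Timedelta("30min"), 0.02)
    assert rec.performed


def _three_test_day(day, bracs):
    """One day with windows at 08/14/20; brac None means omitted."""
    rows = []
    for hour, brac in zip((8, 14, 20), bracs):
        start = pd.Timestamp(f"{day} {hour:02d}:00")
        performed = None if brac is None else start + pd.Timedelta("30min")
        rows.append(("P1", start, start + pd.Timedelta("1h"), performed, brac))
    return rows


def test_aggregate_days_counts_and_max_bac():
    log = make_log(
        _three_test_day("2023-01-02", (0.0, 0.0, 0.0))
        + _three_test_day("2023-01-03", (0.0, None, 0.03))
    )
    days = aggregate_days(log)
    assert list(days["n_omitted"]) == [0, 1]
    assert days["max_bac_permille"].iloc[0] == 0.0
    # max over performed tests of 2.0 x BrAC
    assert days["max_bac_permille"].iloc[1] == pytest.approx(0.06)
    assert (days["n_omitted"] + (days["n_scheduled"] - days["n_omitted"]) == days["n_scheduled"]).all()


def test_aggregate_days_expands_missing_days_as_all_omitted():
    log = make_log(
        _three_test_day("2023-01-02", (0.0, 0.0, 0.0))
        + _three_test_day("2023-01-04", (0.0, 0.0, 0.0))
    )
    days = aggregate_days(log)
    assert len(days) == 3
    middle = days.iloc[1]
    assert middle["n_scheduled"] == 3 and middle["n_omitted"] == 3
    assert np.isnan(middle["max_bac_permille"])
    assert list(days["treatment_day"]) == [0, 1, 2]


def test_aggregate_days_raw_score_decays_during_silence():
    log = make_log(
        _three_test_day("2023-01-02", (0.0, 0.0, 0.0))
        + _three_test_day("2023-01-04", (None, None, None))
        + _three_test_day("2023-01-05", (0.0, 0.0, 0.0))
    )
    days = aggregate_days(log)
    # day 2: streak 1..3 -> scores 5/6,4/6,3/6; day 3: streak 4..6 -> 2/6,1/6,0
    assert days["raw_score"].iloc[1] == pytest.approx(100 * (5 + 4 + 3) / 18)
    assert days["raw_score"].iloc[2] == pytest.approx(100 * (2 + 1 + 0) / 18)
    assert days["raw_score"].iloc[3] == 100.0  # streak resets on performed tests


@pytest.mark.parametrize(
    "bad",
    [
        # unsorted
        _three_test_day("2023-01-03", (0.0, 0.0, 0.0))
        + _three_test_day("2023-01-02", (0.0, 0.0, 0.0)),
        # duplicate window
        _three_test_day("2023-01-02", (0.0, 0.0, 0.0))
        + _three_test_day("2023-01-02", (0.0, 0.0, 0.0)),
    ],
)
def test_aggregate_days_rejects_malformed_logs(bad):
    with pytest.raises(ValidationError):
        aggregate_days(make_log(bad))


def test_aggregate_days_rejects_overlapping_windows():
    start = pd.Timestamp("2023-01-02 08:00")
    log = make_log(
        [
            ("P1", start, start + pd.Timedelta("2h"), None, None),
            ("P1", start + pd.Timedelta("1h"), start + pd.Timedelta("3h"), None, None),
        ]
    )
    with pytest.raises(ValidationError):
        aggregate_days(log)


class TestMtbt:
    def test_within_day_gap(self):
        days = pd.date_range("2023-01-02", periods=1)
        out = compute_mtbt(
            [pd.Timestamp("2023-01-02 08:00"), pd.Timestamp("2023-01-02 20:00")], days
        )
        assert out[0] == pytest.approx(12.0)

    def test_multi_day_gap_attributed_to_every_intersected_day(self):
        days = pd.date_range("2023-01-02", periods=3)
        out = compute_mtbt(
            [pd.Timestamp("2023-01-02 08:00"), pd.Timestamp("2023-01-04 08:00")], days
        )
        np.testing.assert_allclose(out, [48.0, 48.0, 48.0])

    def test_uniform_spacing(self):
        times = pd.date_range("2023-01-02 06:00", periods=9, freq="8h")
        days = pd.date_range("2023-01-02", periods=3)
        np.testing.assert_allclose(compute_mtbt(times, days), [8.0, 8.0, 8.0])

    def test_no_performed_tests_flags_full_span(self):
        days = pd.date_range("2023-01-02", periods=4)
        with pytest.warns(UserWarning, match="no performed tests"):
            out = compute_mtbt([], days)
        np.testing.assert_allclose(out, 96.0)

    def test_deleting_an_interior_test_never_decreases_mtbt(self):
        # interior deletions merge two gaps into a longer one covering both;
        # deleting the first/last test instead removes a boundary gap, which
        # is not counted, so the monotonicity holds for interior tests only
        rng = np.random.default_rng(42)
        days = pd.date_range("2023-01-02", periods=10)
        for _ in range(30):
            hours = np.sort(rng.uniform(0, 240, size=rng.integers(4, 15)))
            times = [pd.Timestamp("2023-01-02") + pd.Timedelta(hours=h) for h in hours]
            base = compute_mtbt(times, days)
            for i in range(1, len(times) - 1):
                reduced = times[:i] + times[i + 1 :]
                new = compute_mtbt(reduced, days)
                mask = ~np.isnan(base) & ~np.isnan(new)
                assert np.all(new[mask] >= base[mask] - 1e-9)


def test_day_table_csv_round_trip(tmp_path, bundle):
    path = tmp_path / "days.csv"
    days = bundle["days"]
    write_day_table(days, path)
    back = read_day_table(path)
    pd.testing.assert_frame_equal(
        back, days.reset_index(drop=True), check_exact=False, rtol=0, atol=1e-12
    )
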