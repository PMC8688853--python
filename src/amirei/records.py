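"""Scheduled breathalyzer test logs and per-day aggregation.

Patients in breathalyzer-based eHealth monitoring perform 2-5 scheduled tests
per day inside notification windows; a test not performed within its window is
an omission.  This module parses test logs, enforces the schedule semantics,
and aggregates tests into per-patient daily records carrying:

* ``max_bac``: the day's highest blood alcohol content (BAC), obtained from
  breath alcohol content (BrAC) by the standard factor-2.0 conversion,
* ``n_omitted``: omitted scheduled tests,
* ``mtbt_hours``: maximum time between tests (MTBT) - the longest gap between
  performed tests attributed to the day, which exceeds 24 h during omission
  streaks,
* ``raw_score``: the 0-100 daily input to the AMI smoothing recurrence.

Calendar days with no logged windows between a patient's first and last
monitored day are expanded to all-omitted days under the configured schedule,
so the AMI decays during device silence.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .ami import AmiParams, daily_raw_score, per_test_score
from .errors import ValidationError

#: BAC (blood) = 2.0 x BrAC (breath), both in permille.
BRAC_TO_BAC_FACTOR = 2.0

TEST_LOG_COLUMNS = [
    "patient_id",
    "window_start",
    "window_end",
    "performed_at",
    "brac_permille",
]

DAY_TABLE_COLUMNS = [
    "patient_id",
    "date",
    "treatment_day",
    "n_scheduled",
    "n_omitted",
    "max_bac_permille",
    "mtbt_hours",
    "raw_score",
    "ddd",
    "peth_umol_l",
]


def brac_to_bac(brac):
    """Convert breath alcohol content (permille) to blood alcohol equivalent.

    BAC = 2.0 x BrAC.  Accepts scalars or arrays; rejects negative input.
    """
    arr = np.asarray(brac, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("BrAC must be non-negative")
    out = BRAC_TO_BAC_FACTOR * arr
    return float(out) if np.isscalar(brac) or arr.ndim == 0 else out


def level_of_quantification(median_bac: float, iqr_bac: float) -> float:
    """Level of quantification of a BAC measurement population.

    Defined as median + 10 x interquartile range; median statistics are robust
    to a minority of drinking measurements, so this estimates the device noise
    floor and motivates the 0.05 permille drinking threshold
    (0.006 + 10 x 0.004 = 0.046 < 0.05).
    """
    if median_bac < 0 or iqr_bac < 0:
        raise ValidationError("median and IQR must be non-negative")
    return median_bac + 10.0 * iqr_bac


@dataclass(frozen=True)
class TestRecord:
    """One scheduled breathalyzer test window for one patient."""

    patient_id: str
    window_start: datetime
    window_end: datetime
    performed_at: datetime | None = None
    brac: float | None = None
    test_index_in_day: int = 0

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ValidationError("window_start must precede window_end")
        if (self.performed_at is None) != (self.brac is None):
            raise ValidationError("brac must be present iff the test was performed")
        if self.performed_at is not None:
            if not (self.window_start <= self.performed_at <= self.window_end):
                raise ValidationError("performed_at must lie within the window")
            if self.brac < 0:
                raise ValidationError("brac must be non-negative")

    @property
    def performed(self) -> bool:
        return self.performed_at is not None


def read_test_log(path) -> pd.DataFrame:
    """Read a test-log CSV (ISO-8601 timestamps, empty performed_at = omitted)."""
    df = pd.read_csv(path)
    missing = [c for c in TEST_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"test log missing columns: {missing}")
    for col in ("window_start", "window_end", "performed_at"):
        df[col] = pd.to_datetime(df[col])
    df["patient_id"] = df["patient_id"].astype(str)
    if (df["brac_permille"].dropna() < 0).any():
        raise ValidationError("negative brac_permille in test log")
    return df


def write_test_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    """Read the optional per-day covariate CSV (patient_id, date, ddd, peth_umol_l)."""
    df = pd.read_csv(path)
    for col in ("patient_id", "date"):
        if col not in df.columns:
            raise ValidationError(f"covariate table missing column {col}")
    df["patient_id"] = df["patient_id"].astype(str)
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    return df


def write_day_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_day_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["patient_id"] = df["patient_id"].astype(str)
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    return df


def compute_mtbt(
    performed_times: Sequence[datetime | pd.Timestamp],
    dates: Sequence[pd.Timestamp],
) -> np.ndarray:
    """Maximum time between tests, attributed per calendar day.

    For each date, MTBT is the longest interval between consecutive performed
    tests among all such intervals intersecting that date, so every day inside
    a multi-day omission gap carries the full gap length.  Gaps to the
    monitoring-period boundaries are not counted; days intersected by no gap
    are NaN.  A patient with zero performed tests gets the full monitored span
    on every day, with a warning.
    """
    dates = pd.DatetimeIndex(pd.to_datetime(list(dates))).normalize()
    times = sorted(pd.to_datetime(list(performed_times)))
    n_days = len(dates)
    if not times:
        warnings.warn(
            "patient has no performed tests; MTBT set to the full monitored span",
            stacklevel=2,
        )
        return np.full(n_days, 24.0 * n_days)
    out = np.full(n_days, np.nan)
    if len(times) < 2:
        return out
    starts = pd.DatetimeIndex(times[:-1])
    ends = pd.DatetimeIndex(times[1:])
    hours = (ends - starts).total_seconds() / 3600.0
    for i, day in enumerate(dates):
        day_end = day + timedelta(days=1)
        mask = (starts < day_end) & (ends > day)
        if mask.any():
            out[i] = hours[mask].max()
    return out


def _check_patient_log(pid: str, grp: pd.DataFrame) -> None:
    ws = grp["window_start"]
    if not ws.is_monotonic_increasing:
        raise ValidationError(f"patient {pid}: test log not sorted by window_start")
    if ws.duplicated().any():
        raise ValidationError(f"patient {pid}: duplicate (patient, window) entries")
    if (grp["window_end"].to_numpy()[:-1] > ws.to_numpy()[1:]).any():
        raise ValidationError(f"patient {pid}: overlapping test windows")
    performed = grp["performed_at"].notna()
    inside = (grp.loc[performed, "performed_at"] >= grp.loc[performed, "window_start"]) & (
        grp.loc[performed, "performed_at"] <= grp.loc[performed, "window_end"]
    )
    if not inside.all():
        raise ValidationError(f"patient {pid}: performed_at outside its window")
    if performed.ne(grp["brac_permille"].notna()).any():
        raise ValidationError(f"patient {pid}: brac present iff performed violated")


def aggregate_days(
    tests: pd.DataFrame,
    schedule: int | None = None,
    params: AmiParams = AmiParams(),
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate a test log into one row per patient-day.

    Parameters
    ----------
    tests
        Test-log table (see :data:`TEST_LOG_COLUMNS`), sorted by patient then
        window_start.
    schedule
        Scheduled tests per day used to expand missing whole days to
        all-omitted; when None the patient's modal logged count is used.
    params
        AMI scoring parameters (BAC threshold, omission horizon).
    covariates
        Optional per-day table with ``ddd`` and/or ``peth_umol_l``.

    Returns
    -------
    Day table with :data:`DAY_TABLE_COLUMNS`; ``raw_score`` is the AMI daily
    input and ``treatment_day`` counts from 0 at each patient's first
    monitored day.
    """
    missing = [c for c in TEST_LOG_COLUMNS if c not in tests.columns]
    if missing:
        raise ValidationError(f"test log missing columns: {missing}")
    rows = []
    for pid, grp in tests.groupby("patient_id", sort=True):
        _check_patient_log(pid, grp)
        grp = grp.assign(_date=grp["window_start"].dt.normalize())
        by_day = {d: g for d, g in grp.groupby("_date")}
        all_days = pd.date_range(grp["_date"].min(), grp["_date"].max(), freq="D")
        default_n = schedule or int(
            grp.groupby("_date").size().mode().iloc[0]
        )
        streak = 0
        for t, day in enumerate(all_days):
            g = by_day.get(day)
            if g is None:
                n_sched = default_n
                scores = []
                for _ in range(n_sched):
                    streak += 1
                    scores.append(
                        per_test_score(
                            False,
                            omission_streak=streak,
                            tests_per_day=n_sched,
                            params=params,
                        )
                    )
                max_bac = np.nan
                n_omitted = n_sched
            else:
                n_sched = len(g)
                scores = []
                bacs = []
                n_omitted = 0
                for _, rec in g.iterrows():
                    if pd.notna(rec["performed_at"]):
                        streak = 0
                        bac = brac_to_bac(float(rec["brac_permille"]))
                        bacs.append(bac)
                        scores.append(
                            per_test_score(True, bac=bac, params=params)
                        )
                    else:
                        streak += 1
                        n_omitted += 1
                        scores.append(
                            per_test_score(
                                False,
                                omission_streak=streak,
                                tests_per_day=n_sched,
                                params=params,
                            )
                        )
                max_bac = max(bacs) if bacs else np.nan
            rows.append(
                {
                    "patient_id": pid,
                    "date": day,
                    "treatment_day": t,
                    "n_scheduled": n_sched,
                    "n_omitted": n_omitted,
                    "max_bac_permille": max_bac,
                    "mtbt_hours": np.nan,
                    "raw_score": daily_raw_score(scores),
                }
            )
        performed_times = grp.loc[grp["performed_at"].notna(), "performed_at"]
        mtbt = compute_mtbt(performed_times.tolist(), all_days)
        for i in range(len(all_days)):
            rows[len(rows) - len(all_days) + i]["mtbt_hours"] = mtbt[i]
    out = pd.DataFrame(rows)
    if covariates is not None:
        cov = covariates.copy()
        cov["date"] = pd.to_datetime(cov["date"]).dt.normalize()
        keep = [c for c in ("ddd", "peth_umol_l") if c in cov.columns]
        out = out.merge(
            cov[["patient_id", "date"] + keep], on=["patient_id", "date"], how="left"
        )
    for col in ("ddd", "peth_umol_l"):
        if col not in out.columns:
            out[col] = np.nan
    return out[DAY_TABLE_COLUMNS]
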