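"""Addiction Monitoring Index (AMI) engine.

The AMI is a 0-100 digital biomarker summarising a patient's daily
sobriety/compliance status from scheduled breathalyzer tests.  Each scheduled
test contributes a score in [0, 1]:

* performed with blood alcohol content (BAC) below the drinking threshold
  (default 0.05 permille) -> 1,
* performed at or above the threshold -> 0,
* omitted -> an imputed value that decays linearly with the length of the
  ongoing omission streak, reaching the positive-test weight (0) once the
  streak spans 48 hours of scheduled tests.

The per-day mean of these scores, scaled to 0-100, is the raw daily score
``x_t``, which is exponentially smoothed::

    s_0 = x_0
    s_t = alpha * x_t + (1 - alpha) * s_{t-1}

AMI-N denotes the series with smoothing factor ``alpha = N / 100``; small
alphas (AMI-6) give a long-memory baseline, large alphas (AMI-45) track
short-term change.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Named smoothing factors used throughout: alpha = N / 100.
DEFAULT_ALPHA_NAMES: tuple[int, ...] = (6, 12, 21, 45)


@dataclass(frozen=True)
class AmiParams:
    """Parameters of the AMI per-test scoring rule.

    Parameters
    ----------
    alpha
        Smoothing factor in (0, 1].
    bac_threshold
        Blood alcohol content (permille) at or above which a performed test
        counts as drinking.  Default 0.05 permille.
    scale_max
        Top of the AMI scale (fixed at 100).
    omission_horizon_hours
        Streak length, in hours of scheduled testing, after which an omitted
        test carries the same weight as a positive test.  Default 48 h.
    """

    alpha: float = 0.21
    bac_threshold: float = 0.05
    scale_max: float = 100.0
    omission_horizon_hours: float = 48.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.bac_threshold <= 0:
            raise ValidationError(
                f"bac_threshold must be positive, got {self.bac_threshold}"
            )
        if self.omission_horizon_hours <= 0:
            raise ValidationError("omission_horizon_hours must be positive")


@dataclass(frozen=True)
class BiomarkerSeries:
    """Per-day smoothed AMI values for one patient and one alpha."""

    patient_id: str
    alpha: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValidationError("values must be one-dimensional")


def per_test_score(
    performed: bool,
    bac: float | None = None,
    omission_streak: int = 0,
    tests_per_day: int = 3,
    params: AmiParams = AmiParams(),
) -> float:
    """Score a single scheduled test in [0, 1].

    Parameters
    ----------
    performed
        Whether the test was performed within its window.
    bac
        Blood alcohol content (permille) of a performed test.
    omission_streak
        For an omitted test, the ongoing count of consecutively omitted
        scheduled tests up to and including this one.  Streaks span day
        boundaries and reset on any performed test.
    tests_per_day
        Scheduled tests per day; the 48-h horizon therefore spans
        ``2 * tests_per_day`` tests.
    """
    if performed:
        if omission_streak:
            raise ValidationError(
                "omission_streak must be 0 for a performed test"
            )
        if bac is None or bac < 0:
            raise ValidationError("performed test requires a non-negative BAC")
        return 1.0 if bac < params.bac_threshold else 0.0
    if omission_streak < 1:
        raise ValidationError("omitted test requires omission_streak >= 1")
    horizon_tests = tests_per_day * params.omission_horizon_hours / 24.0
    return max(0.0, 1.0 - omission_streak / horizon_tests)


def daily_raw_score(scores: Sequence[float]) -> float:
    """Raw daily score ``x_t``: mean of the day's per-test scores, on 0-100."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValidationError("a day must have at least one scheduled test")
    if np.any((arr < 0) | (arr > 1)):
        raise ValidationError("per-test scores must lie in [0, 1]")
    return 100.0 * float(arr.mean())


def exp_smooth(x: Sequence[float], alpha: float) -> np.ndarray:
    """Exponential smoothing: s_0 = x_0, s_t = alpha*x_t + (1-alpha)*s_{t-1}."""
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValidationError("series must be non-empty")
    return pd.Series(arr).ewm(alpha=alpha, adjust=False).mean().to_numpy()


def compute_ami_family(
    day_table: pd.DataFrame,
    names: Iterable[int] = DEFAULT_ALPHA_NAMES,
) -> pd.DataFrame:
    """Smooth each patient's raw scores at every requested alpha.

    Parameters
    ----------
    day_table
        Day-level table with at least ``patient_id``, ``date``,
        ``treatment_day`` and ``raw_score`` columns; treatment days must be
        contiguous (0, 1, 2, ...) within each patient.
    names
        AMI names N; each yields a column ``ami_<N>`` with alpha = N/100.

    Returns
    -------
    DataFrame with patient_id, date, treatment_day and one ami_<N> column per
    requested alpha, row-aligned with ``day_table``.
    """
    names = list(names)
    if not names:
        raise ValidationError("at least one alpha name is required")
    out = day_table[["patient_id", "date", "treatment_day"]].copy()
    for col in (f"ami_{n}" for n in names):
        out[col] = np.nan
    for pid, grp in day_table.groupby("patient_id", sort=False):
        td = grp["treatment_day"].to_numpy()
        if td.size and (td[0] != 0 or np.any(np.diff(td) != 1)):
            raise ValidationError(
                f"patient {pid}: treatment days must be contiguous from 0"
            )
        x = grp["raw_score"].to_numpy(dtype=float)
        for n in names:
            out.loc[grp.index, f"ami_{n}"] = exp_smooth(x, n / 100.0)
    return out


def biomarker_series(
    ami_table: pd.DataFrame, patient_id: str, name: int
) -> BiomarkerSeries:
    """Extract one patient's AMI-``name`` series from a family table."""
    grp = ami_table[ami_table["patient_id"] == patient_id]
    col = f"ami_{name}"
    if grp.empty or col not in ami_table.columns:
        raise ValidationError(f"no AMI-{name} series for patient {patient_id}")
    return BiomarkerSeries(
        patient_id=patient_id, alpha=name / 100.0, values=grp[col].to_numpy()
    )
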