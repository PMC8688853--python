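"""Recovery and Exacerbation Index (REI) and exacerbation events (EEs).

The REI is the ratio of a short-memory AMI (default AMI-45) to a long-memory
AMI (default AMI-6).  REI < 1 means the patient is faring worse in the short
term than the long term, independent of the absolute sobriety/compliance
level.  A maximal run of consecutive days with REI below a threshold (default
0.8, strict) is an exacerbation event - the measurement-based replacement for
the binary lapse/relapse construct.  Event lists are summarised per patient in
the style of a clinical characteristics table: number of events, percentage of
days in events (%EE), mean/max event length, mean time since the previous
event.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_REI_THRESHOLD = 0.8
DEFAULT_REI_CAP = 10.0
DEFAULT_NUMERATOR = 45
DEFAULT_DENOMINATOR = 6


@dataclass(frozen=True)
class ExacerbationEvent:
    """A maximal run of consecutive days with REI below threshold.

    ``start_day`` / ``end_day`` are inclusive treatment-day indices;
    ``dist_previous`` is the number of days from the previous event's end to
    this event's start (None for a patient's first event).
    """

    start_day: int
    end_day: int
    dist_previous: int | None = None

    def __post_init__(self) -> None:
        if self.end_day < self.start_day:
            raise ValidationError("end_day must be >= start_day")
        if self.dist_previous is not None and self.dist_previous < 1:
            raise ValidationError("dist_previous must be >= 1 when present")

    @property
    def length(self) -> int:
        return self.end_day - self.start_day + 1


@dataclass
class PatientSummary:
    """Per-patient compilation of monitoring and exacerbation-event statistics."""

    patient_id: str
    treatment_days: int
    percent_ee: float
    ee_count: int
    mean_ee_length: float | None
    max_ee_length: int | None
    mean_dist_previous: float | None
    ami21_mean: float | None
    mtbt_mean: float | None
    ddd_mean: float | None
    peth_mean: float | None


def compute_rei(
    ami_short: Sequence[float],
    ami_long: Sequence[float],
    cap: float = DEFAULT_REI_CAP,
) -> np.ndarray:
    """Per-day REI = short-memory AMI / long-memory AMI.

    Because smoothing weights are strictly positive, the long-memory value can
    only be 0 when every raw score so far was 0, in which case the short-memory
    value is 0 too; that 0/0 day is assigned REI = 1 by convention.  Values are
    capped at ``cap`` (deep dives followed by rapid recovery send the raw
    ratio far above 1; the cap stabilises plots and threshold scans without
    affecting event detection, which only uses the region below threshold).
    """
    s = np.asarray(ami_short, dtype=float)
    l = np.asarray(ami_long, dtype=float)
    if s.shape != l.shape:
        raise ValidationError("numerator and denominator series are misaligned")
    zero = l == 0
    if np.any(zero & (s != 0)):
        raise ValidationError(
            "long-memory AMI is 0 where short-memory AMI is not; "
            "series do not share a raw-score history"
        )
    rei = np.ones_like(s)
    np.divide(s, l, out=rei, where=~zero)
    return np.minimum(rei, cap)


def detect_events(
    rei: Sequence[float], threshold: float = DEFAULT_REI_THRESHOLD
) -> list[ExacerbationEvent]:
    """Segment an REI series into exacerbation events.

    An event is a maximal run of consecutive days with REI strictly below
    ``threshold``; a day exactly at the threshold is outside any event.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    values = np.asarray(rei, dtype=float)
    below = values < threshold
    events: list[ExacerbationEvent] = []
    prev_end: int | None = None
    start: int | None = None
    for i, flag in enumerate(np.append(below, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            end = i - 1
            dist = None if prev_end is None else start - prev_end
            events.append(ExacerbationEvent(start, end, dist))
            prev_end = end
            start = None
    return events


def events_to_frame(
    events: Sequence[ExacerbationEvent],
    patient_id: str,
    dates: Sequence[pd.Timestamp] | None = None,
) -> pd.DataFrame:
    """Tabulate events (start/end date when the day->date mapping is given)."""
    rows = []
    for ev in events:
        rows.append(
            {
                "patient_id": patient_id,
                "start_day": ev.start_day,
                "end_day": ev.end_day,
                "start_date": dates[ev.start_day] if dates is not None else pd.NaT,
                "end_date": dates[ev.end_day] if dates is not None else pd.NaT,
                "length_days": ev.length,
                "dist_previous_days": ev.dist_previous,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "start_day",
            "end_day",
            "start_date",
            "end_date",
            "length_days",
            "dist_previous_days",
        ],
    )


def in_event_mask(
    events: Sequence[ExacerbationEvent], n_days: int
) -> np.ndarray:
    """Boolean day-level indicator of exacerbation-event membership."""
    mask = np.zeros(n_days, dtype=bool)
    for ev in events:
        mask[ev.start_day : ev.end_day + 1] = True
    return mask


def summarize_patient(
    days: pd.DataFrame,
    ami21: Sequence[float] | None,
    events: Sequence[ExacerbationEvent],
    min_event_length: int = 1,
) -> PatientSummary:
    """Compile a patient's monitoring and event statistics.

    ``min_event_length`` filters short events before summarising (a display
    value of 2 suppresses single-day events).  The mean distance to the
    previous event excludes the first event, whose distance is undefined.
    """
    n_days = len(days)
    if n_days == 0:
        raise ValidationError("patient has zero monitored days")
    kept = [ev for ev in events if ev.length >= min_event_length]
    lengths = [ev.length for ev in kept]
    dists = [ev.dist_previous for ev in kept if ev.dist_previous is not None]
    ami_vals = None if ami21 is None else np.asarray(ami21, dtype=float)

    def _mean(series: pd.Series) -> float | None:
        m = series.dropna()
        return float(m.mean()) if len(m) else None

    return PatientSummary(
        patient_id=str(days["patient_id"].iloc[0]),
        treatment_days=n_days,
        percent_ee=100.0 * sum(lengths) / n_days,
        ee_count=len(kept),
        mean_ee_length=float(np.mean(lengths)) if lengths else None,
        max_ee_length=max(lengths) if lengths else None,
        mean_dist_previous=float(np.mean(dists)) if dists else None,
        ami21_mean=float(ami_vals.mean()) if ami_vals is not None else None,
        mtbt_mean=_mean(days["mtbt_hours"]) if "mtbt_hours" in days else None,
        ddd_mean=_mean(days["ddd"]) if "ddd" in days else None,
        peth_mean=_mean(days["peth_umol_l"]) if "peth_umol_l" in days else None,
    )
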