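"""REI threshold selection by ANOVA scan.

For each candidate REI threshold, days with a drinks-per-drinking-day (DDD)
observation are split into two bins - inside an exacerbation event (REI below
threshold) or outside - and the mean DDD difference between bins is summarised
by the ANOVA F-ratio, both from a one-way model and from a two-way model with
patient as a categorical fixed factor.  Plotted over the grid, the F-ratio is
low at both extremes (degenerate bins) and peaks where the threshold best
separates drinking intensity; the argmax is the recommended threshold.

No multiplicity correction is applied across the grid; picking the maximal F
inflates the apparent significance of the winning threshold, and the test
suite quantifies that inflation on null data instead of hiding it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError

DEFAULT_GRID = np.linspace(0.05, 1.1, 17)


@dataclass
class ScanResult:
    """F-ratio per candidate threshold.

    ``table`` columns: threshold, f_plain (one-way), f_patient (patient fixed
    factor), n_bin0, n_bin1.  F is NaN where a bin is empty.
    """

    table: pd.DataFrame


@dataclass(frozen=True)
class ThresholdChoice:
    threshold: float
    f_ratio: float
    used_patient_factor: bool
    plateau_low: float
    plateau_high: float


def scan_thresholds(
    day_rei: pd.DataFrame, grid: np.ndarray | None = None
) -> ScanResult:
    """ANOVA F-ratio of DDD between in-event and out-of-event days, per threshold.

    Parameters
    ----------
    day_rei
        Day-level table with ``patient_id``, ``rei`` and ``ddd`` columns; rows
        without a DDD observation are excluded.
    grid
        Candidate thresholds; default 17 equally spaced values on [0.05, 1.1].
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    for col in ("patient_id", "rei", "ddd"):
        if col not in day_rei.columns:
            raise ValidationError(f"day table missing column {col}")
    data = day_rei.dropna(subset=["ddd", "rei"]).copy()
    rows = []
    for tau in grid:
        data["in_ee"] = (data["rei"] < tau).astype(int)
        n1 = int(data["in_ee"].sum())
        n0 = len(data) - n1
        f_plain = f_patient = np.nan
        if n0 > 0 and n1 > 0:
            ols_a = smf.ols("ddd ~ C(in_ee)", data=data).fit()
            f_plain = float(sm.stats.anova_lm(ols_a, typ=2).loc["C(in_ee)", "F"])
            if data["patient_id"].nunique() > 1:
                ols_b = smf.ols("ddd ~ C(in_ee) + C(patient_id)", data=data).fit()
                f_patient = float(
                    sm.stats.anova_lm(ols_b, typ=2).loc["C(in_ee)", "F"]
                )
            else:
                f_patient = f_plain
        rows.append(
            {
                "threshold": float(tau),
                "f_plain": f_plain,
                "f_patient": f_patient,
                "n_bin0": n0,
                "n_bin1": n1,
            }
        )
    return ScanResult(table=pd.DataFrame(rows))


def select_threshold(
    scan: ScanResult, prefer_patient_factor: bool = True
) -> ThresholdChoice:
    """Pick the F-maximising threshold (ties broken toward the smaller value).

    The plateau bounds report the grid range whose F-ratio stays within 80% of
    the maximum - the band of near-equivalent thresholds around the peak.
    """
    t = scan.table
    col = "f_patient" if prefer_patient_factor and t["f_patient"].notna().any() else "f_plain"
    valid = t.dropna(subset=[col])
    if len(valid) < 3:
        raise ValidationError("need at least 3 thresholds with a defined F-ratio")
    fmax = valid[col].max()
    best = valid[valid[col] == fmax].iloc[0]
    plateau = valid[valid[col] >= 0.8 * fmax]["threshold"]
    return ThresholdChoice(
        threshold=float(best["threshold"]),
        f_ratio=float(fmax),
        used_patient_factor=(col == "f_patient"),
        plateau_low=float(plateau.min()),
        plateau_high=float(plateau.max()),
    )
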