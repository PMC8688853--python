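"""Cohort periodicity of exacerbation events.

Day-level in-event indicators are analysed against calendar factors - weekday,
ISO-8601 week number (holiday seasonality) and treatment-day bin (time in
treatment).  Per-level %EE with Wald 95% confidence bars serves visualisation;
formal inference uses logistic regression of the day-level indicator on the
factor with patient-clustered (sandwich) covariance, the standard way to
handle repeated measures by patient without modelling the within-patient
correlation.  The joint factor test applies the Hotelling-style small-sample
correction to the robust Wald statistic W: F = (G-q) / (q (G-1)) * W referred
to F(q, G-q), with G the number of patient clusters and q the constraint
count; uncorrected multi-constraint cluster Wald tests over-reject at
moderate G.  When G <= q the correction is undefined and the asymptotic
chi-square reference is used with a warning.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError

FACTORS = ("weekday", "iso_week", "treatment_bin")
WEEKDAY_ORDER = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
DEFAULT_BIN_WIDTH = 30
DEFAULT_MAX_TREATMENT_DAY = 390


@dataclass
class PeriodicityTest:
    """Joint cluster-robust test of a calendar factor plus per-level effects."""

    factor: str
    statistic: float  # robust Wald chi-square of the factor block
    df: int
    df_denom: int  # G - q (Hotelling correction); 0 when chi-square fallback
    pvalue: float
    effects: pd.DataFrame  # level, odds_ratio, ci_low, ci_high (vs reference)
    dropped_levels: list = field(default_factory=list)


def build_cohort_table(
    day_table: pd.DataFrame,
    in_ee: np.ndarray | pd.Series,
    bin_width: int = DEFAULT_BIN_WIDTH,
    max_treatment_day: int = DEFAULT_MAX_TREATMENT_DAY,
) -> pd.DataFrame:
    """Attach calendar factors to a day table with an in-event indicator.

    ``treatment_bin`` covers [0, max_treatment_day) in ``bin_width``-day bins;
    later days get a missing bin and drop out of treatment-time analyses only.
    """
    if len(day_table) != len(in_ee):
        raise ValidationError("in_ee indicator misaligned with day table")
    out = day_table[["patient_id", "date", "treatment_day"]].copy()
    out["in_ee"] = np.asarray(in_ee, dtype=int)
    dates = pd.to_datetime(out["date"])
    out["weekday"] = pd.Categorical(
        dates.dt.strftime("%a"), categories=list(WEEKDAY_ORDER), ordered=True
    )
    out["iso_week"] = dates.dt.isocalendar().week.astype(int)
    td = out["treatment_day"].to_numpy()
    bins = np.where(td < max_treatment_day, td // bin_width, -1).astype(float)
    bins[bins < 0] = np.nan
    out["treatment_bin"] = bins
    return out


def percent_ee_by(table: pd.DataFrame, factor: str) -> pd.DataFrame:
    """%EE per factor level with a 95% Wald interval on the day-level proportion.

    The interval describes sampling noise for visualisation; it ignores
    patient clustering, so inference should come from
    :func:`cluster_logistic_test`.
    """
    if factor not in FACTORS:
        raise ValidationError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    if table.empty:
        raise ValidationError("cohort table is empty")
    work = table.dropna(subset=[factor])
    rows = []
    for level, grp in work.groupby(factor, observed=True):
        n = len(grp)
        p = grp["in_ee"].mean()
        half = 1.96 * np.sqrt(p * (1 - p) / n)
        rows.append(
            {
                "level": level,
                "n_days": n,
                "n_patients": grp["patient_id"].nunique(),
                "percent_ee": 100.0 * p,
                "ci_low": 100.0 * max(0.0, p - half),
                "ci_high": 100.0 * min(1.0, p + half),
            }
        )
    return pd.DataFrame(rows)


def cluster_logistic_test(table: pd.DataFrame, factor: str) -> PeriodicityTest:
    """Joint test of a calendar factor on the in-event indicator.

    Fits ``in_ee ~ C(factor)`` by binomial GLM with patient-clustered sandwich
    covariance; separated levels (all days in or all days out of events) are
    dropped from the fit with a warning.  Per-level odds ratios are relative
    to the first remaining level, with robust 95% intervals.
    """
    if factor not in FACTORS:
        raise ValidationError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    work = table.dropna(subset=[factor]).copy()
    level_means = work.groupby(factor, observed=True)["in_ee"].mean()
    if len(level_means) < 2:
        raise ValidationError("factor must have at least 2 observed levels")
    dropped = [lv for lv, m in level_means.items() if m in (0.0, 1.0)]
    if dropped:
        warnings.warn(
            f"levels {dropped} of {factor} are separated (all-0 or all-1); "
            "dropped from the joint test",
            stacklevel=2,
        )
        work = work[~work[factor].isin(dropped)]
        if work[factor].nunique() < 2:
            raise ValidationError(
                "fewer than 2 non-separated levels; joint test undefined"
            )
    work["_level"] = work[factor].astype(str)
    order = [
        str(lv) for lv in level_means.index if str(lv) in set(work["_level"])
    ]
    work["_level"] = pd.Categorical(work["_level"], categories=order)
    res = smf.glm(
        "in_ee ~ C(_level)", data=work, family=sm.families.Binomial()
    ).fit(cov_type="cluster", cov_kwds={"groups": work["patient_id"]})
    names = [n for n in res.params.index if n.startswith("C(_level)")]
    wald = res.wald_test(names, scalar=True)
    chi2 = float(wald.statistic)
    q = len(names)
    n_groups = work["patient_id"].nunique()
    if n_groups > q:
        df_denom = n_groups - q
        f_stat = (n_groups - q) / (q * (n_groups - 1)) * chi2
        pvalue = float(scipy.stats.f.sf(f_stat, q, df_denom))
    else:
        warnings.warn(
            f"only {n_groups} clusters for {q} constraints; using the "
            "asymptotic chi-square reference",
            stacklevel=2,
        )
        df_denom = 0
        pvalue = float(scipy.stats.chi2.sf(chi2, q))
    ci = res.conf_int()
    effects = pd.DataFrame(
        {
            "level": [order[0]] + [n.split("[T.")[1][:-1] for n in names],
            "odds_ratio": [1.0] + list(np.exp(res.params[names])),
            "ci_low": [np.nan] + list(np.exp(ci.loc[names, 0])),
            "ci_high": [np.nan] + list(np.exp(ci.loc[names, 1])),
        }
    )
    return PeriodicityTest(
        factor=factor,
        statistic=chi2,
        df=q,
        df_denom=df_denom,
        pvalue=pvalue,
        effects=effects,
        dropped_levels=dropped,
    )
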