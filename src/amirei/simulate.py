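"""Synthetic breathalyzer cohorts with known ground truth.

Real monitoring data from alcohol-use-disorder eHealth programmes are not
publicly shareable, so every analysis stage in this package is exercised on
simulated cohorts whose drinking behaviour is known exactly.  Each patient
follows an archetype (abstinent, controlled, weekend binger, periodic heavy,
chaotic) that sets a daily drinking propensity on the logit scale:

    logit P(drink on day t) = base + weekday effect + ISO-week effect
                              + treatment-time ramp + gain * z_{t-1}

where the latent episode state z follows an AR(1) recursion driven by past
drinking, so high persistence produces multi-day to month-long drinking
episodes.  Drinking days draw a lognormal drinks-per-drinking-day (DDD) and
place above-threshold blood alcohol values at one or more of the day's 2-5
scheduled test windows (evening windows first); test omission is Bernoulli
per window with a higher probability on drinking days, encoding the coupling
between poor compliance and drinking.  A pseudo-PEth covariate is a 21-day
moving average of daily drinks times a calibration constant plus noise -
a low-time-resolution cumulative-intake biomarker.

Per-patient randomness derives from the master seed through
``numpy.random.SeedSequence(master_seed, spawn_key=(patient_index,))``, so any
patient can be regenerated independently.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .errors import ValidationError

#: pseudo-PEth: umol/L per (drink/day) of 21-day average intake
PETH_PER_DRINK = 0.08
PETH_WINDOW_DAYS = 21
PETH_NOISE_SD = 0.02
#: sober-test BrAC noise: lognormal with BAC median ~0.006 permille
SOBER_BRAC_MEDIAN = 0.003
SOBER_BRAC_SIGMA = 0.5
#: probability a drinking / sober day contributes a DDD observation
DDD_REPORT_DRINKING = 0.9
DDD_REPORT_SOBER = 0.3

ARCHETYPE_NAMES = (
    "abstinent",
    "controlled",
    "weekend_binger",
    "periodic_heavy",
    "chaotic",
)


def _weekend(sat: float, sun: float, fri: float = 0.0) -> tuple[float, ...]:
    return (0.0, 0.0, 0.0, 0.0, fri, sat, sun)


def _holiday_weeks(amount: float) -> tuple[float, ...]:
    w = np.zeros(53)
    for wk in (1, 25, 26, 52, 53):  # new year, midsummer, christmas
        w[wk - 1] = amount
    return tuple(w)


@dataclass(frozen=True)
class ArchetypeConfig:
    """Generative parameters for one simulated patient.

    ``weekday_logits`` is indexed Monday=0..Sunday=6; ``week_logits`` by ISO
    week number minus 1.  ``ramp_peak_day`` / ``ramp_amplitude`` define a
    piecewise-linear treatment-time effect rising to its peak and decaying
    over ~300 days afterwards.  ``episode_persistence`` is the AR(1)
    coefficient (time constant) of the latent episode state in [0, 1);
    ``episode_gain`` scales its logit contribution, so gain controls how
    strongly an active episode sustains itself and persistence how slowly it
    decays.
    """

    name: str
    base_logit: float
    weekday_logits: tuple[float, ...] = (0.0,) * 7
    week_logits: tuple[float, ...] = (0.0,) * 53
    ramp_peak_day: int = 105
    ramp_amplitude: float = 0.0
    episode_persistence: float = 0.0
    episode_gain: float = 4.0
    ddd_mu: float = np.log(4.0)
    ddd_sigma: float = 0.5
    omission_base: float = 0.05
    omission_drinking: float = 0.3
    tests_per_day: int = 3
    n_days: int = 365
    seed: int = 0
    start_date: date = date(2023, 1, 2)  # a Monday

    def __post_init__(self) -> None:
        if len(self.weekday_logits) != 7 or len(self.week_logits) != 53:
            raise ValidationError("need 7 weekday and 53 week logits")
        for p in (self.omission_base, self.omission_drinking):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("omission probabilities must be in [0, 1]")
        if not (2 <= self.tests_per_day <= 5):
            raise ValidationError("tests_per_day must be in [2, 5]")
        if not (0.0 <= self.episode_persistence < 1.0):
            raise ValidationError("episode_persistence must be in [0, 1)")
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")


ARCHETYPES: dict[str, ArchetypeConfig] = {
    "abstinent": ArchetypeConfig(
        name="abstinent",
        base_logit=-12.0,
        omission_base=0.05,
        omission_drinking=0.3,
    ),
    "controlled": ArchetypeConfig(
        name="controlled",
        base_logit=-2.5,
        weekday_logits=_weekend(0.7, 0.5, 0.4),
        episode_persistence=0.2,
        episode_gain=1.0,
        ddd_mu=np.log(2.0),
        ddd_sigma=0.4,
        omission_base=0.05,
        omission_drinking=0.15,
    ),
    "weekend_binger": ArchetypeConfig(
        name="weekend_binger",
        base_logit=-3.5,
        weekday_logits=_weekend(2.5, 2.5, 1.0),
        week_logits=_holiday_weeks(1.0),
        episode_persistence=0.3,
        episode_gain=1.2,
        ddd_mu=np.log(6.0),
        ddd_sigma=0.5,
        omission_base=0.05,
        omission_drinking=0.35,
    ),
    "periodic_heavy": ArchetypeConfig(
        name="periodic_heavy",
        base_logit=-2.8,
        week_logits=_holiday_weeks(1.0),
        ramp_amplitude=0.8,
        episode_persistence=0.9,
        ddd_mu=np.log(10.0),
        ddd_sigma=0.4,
        omission_base=0.05,
        omission_drinking=0.5,
    ),
    "chaotic": ArchetypeConfig(
        name="chaotic",
        base_logit=-1.2,
        episode_persistence=0.4,
        episode_gain=2.5,
        ddd_mu=np.log(8.0),
        ddd_sigma=0.7,
        omission_base=0.25,
        omission_drinking=0.5,
    ),
}


def make_archetype(name: str, **overrides) -> ArchetypeConfig:
    """A preset archetype with optional field overrides."""
    if name not in ARCHETYPES:
        raise ValidationError(f"unknown archetype {name!r}; choose from {ARCHETYPE_NAMES}")
    return replace(ARCHETYPES[name], **overrides)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _ramp(t: np.ndarray, peak: int, amplitude: float) -> np.ndarray:
    rise = np.minimum(t / max(peak, 1), 1.0)
    decay = np.maximum(t - peak, 0) / 300.0
    return amplitude * np.maximum(rise - decay, 0.0)


def drinking_probabilities(cfg: ArchetypeConfig, z_prev: float, day_index: int) -> float:
    """Logit-model drinking probability for one day given the latent state."""
    d = cfg.start_date + timedelta(days=int(day_index))
    iso_week = d.isocalendar()[1]
    logit = (
        cfg.base_logit
        + cfg.weekday_logits[d.weekday()]
        + cfg.week_logits[iso_week - 1]
        + float(_ramp(np.array([day_index]), cfg.ramp_peak_day, cfg.ramp_amplitude)[0])
        + cfg.episode_gain * z_prev
    )
    return float(_sigmoid(logit))


def simulate_patient(
    cfg: ArchetypeConfig, patient_id: str = "P0001"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one patient's test log and per-day ground truth.

    Returns
    -------
    tests
        Test-log table in the standard dialect (patient_id, window_start,
        window_end, performed_at, brac_permille), one row per scheduled window.
    truth
        Per-day table: patient_id, date, drank (0/1), drinks (0 when sober),
        ddd (observed drinks-per-drinking-day, NaN when unreported) and
        peth_umol_l (pseudo-PEth, reported daily).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_days
    tpd = cfg.tests_per_day
    window_starts_h = np.linspace(8.0, 20.0, tpd)

    drank = np.zeros(n, dtype=int)
    drinks = np.zeros(n)
    z = 0.0
    for t in range(n):
        p = drinking_probabilities(cfg, z, t)
        drank[t] = rng.random() < p
        if drank[t]:
            drinks[t] = rng.lognormal(cfg.ddd_mu, cfg.ddd_sigma)
        z = cfg.episode_persistence * z + (1.0 - cfg.episode_persistence) * drank[t]

    test_rows = []
    for t in range(n):
        day = pd.Timestamp(cfg.start_date) + pd.Timedelta(days=t)
        if drank[t]:
            n_pos = 1 + rng.binomial(tpd - 1, min(0.8, drinks[t] / 12.0))
            positive = np.zeros(tpd, dtype=bool)
            positive[tpd - n_pos :] = True  # evening drinking
            p_omit = cfg.omission_drinking
        else:
            positive = np.zeros(tpd, dtype=bool)
            p_omit = cfg.omission_base
        for j in range(tpd):
            start = day + pd.Timedelta(hours=window_starts_h[j])
            end = start + pd.Timedelta(hours=1)
            omitted = rng.random() < p_omit
            if omitted:
                performed_at = pd.NaT
                brac = np.nan
            else:
                performed_at = start + pd.Timedelta(hours=float(rng.random()))
                if positive[j]:
                    bac = rng.uniform(0.06, min(3.0, 0.1 + 0.12 * drinks[t]))
                    brac = bac / 2.0
                else:
                    brac = rng.lognormal(np.log(SOBER_BRAC_MEDIAN), SOBER_BRAC_SIGMA)
            test_rows.append(
                {
                    "patient_id": patient_id,
                    "window_start": start,
                    "window_end": end,
                    "performed_at": performed_at,
                    "brac_permille": brac,
                }
            )

    avg = (
        pd.Series(drinks).rolling(PETH_WINDOW_DAYS, min_periods=1).mean().to_numpy()
    )
    peth = np.maximum(avg * PETH_PER_DRINK + rng.normal(0, PETH_NOISE_SD, n), 0.0)
    report = np.where(
        drank == 1,
        rng.random(n) < DDD_REPORT_DRINKING,
        rng.random(n) < DDD_REPORT_SOBER,
    )
    ddd_obs = np.where(report, drinks, np.nan)
    truth = pd.DataFrame(
        {
            "patient_id": patient_id,
            "date": pd.date_range(pd.Timestamp(cfg.start_date), periods=n, freq="D"),
            "drank": drank,
            "drinks": drinks,
            "ddd": ddd_obs,
            "peth_umol_l": peth,
        }
    )
    return pd.DataFrame(test_rows), truth


def patient_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Counter-based per-patient seed: SeedSequence(master, spawn_key=(index,))."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def simulate_cohort(
    n_patients: int,
    mix: dict[str, float] | str = "weekend_binger",
    seed: int = 0,
    n_days: int = 365,
    **overrides,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort test log and ground-truth table.

    ``mix`` maps archetype names to proportions summing to 1 (or names one
    archetype); patient counts per archetype use largest-remainder rounding so
    the assignment is deterministic.  Patient ``i`` draws its randomness from
    :func:`patient_seed`.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    if isinstance(mix, str):
        mix = {mix: 1.0}
    if not mix:
        raise ValidationError("archetype mix must be non-empty")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValidationError("mix proportions must sum to 1")
    names = sorted(mix)
    exact = {a: mix[a] * n_patients for a in names}
    counts = {a: int(np.floor(exact[a])) for a in names}
    for a in sorted(names, key=lambda a: exact[a] - counts[a], reverse=True):
        if sum(counts.values()) >= n_patients:
            break
        counts[a] += 1
    assignment = [a for a in names for _ in range(counts[a])]

    tests, truths = [], []
    for i, arch in enumerate(assignment):
        child = int(patient_seed(seed, i).generate_state(1)[0])
        cfg = make_archetype(arch, n_days=n_days, seed=child, **overrides)
        pid = f"P{i + 1:04d}"
        t, tr = simulate_patient(cfg, patient_id=pid)
        tr = tr.assign(archetype=arch)
        tests.append(t)
        truths.append(tr)
    return pd.concat(tests, ignore_index=True), pd.concat(truths, ignore_index=True)


def simulate_ee_table(
    n_patients: int,
    n_days: int,
    weekday_logits: tuple[float, ...] = (0.0,) * 7,
    base_logit: float = -1.5,
    patient_sd: float = 0.8,
    seed: int = 0,
    start_date: date = date(2023, 1, 2),
) -> pd.DataFrame:
    """Directly simulate a cohort day table of in-event indicators.

    A patient-random-intercept Bernoulli model: logit P(in EE) = base +
    patient intercept + weekday effect.  Used for calibration studies of the
    periodicity tests, where the weekday odds ratio must be controlled
    exactly (the full breathalyzer simulator only controls it indirectly).
    """
    if n_patients < 1 or n_days < 1:
        raise ValidationError("n_patients and n_days must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    intercepts = rng.normal(0.0, patient_sd, n_patients)
    dates = pd.date_range(pd.Timestamp(start_date), periods=n_days, freq="D")
    wd = dates.weekday.to_numpy()
    rows = []
    for i in range(n_patients):
        logit = base_logit + intercepts[i] + np.asarray(weekday_logits)[wd]
        in_ee = (rng.random(n_days) < _sigmoid(logit)).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": f"P{i + 1:04d}",
                    "date": dates,
                    "treatment_day": np.arange(n_days),
                    "in_ee": in_ee,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    from .periodicity import build_cohort_table

    return build_cohort_table(
        table[["patient_id", "date", "treatment_day"]], table["in_ee"]
    )
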