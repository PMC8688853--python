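"""End-to-end pipeline: test log -> day table -> AMI -> REI -> events -> summaries."""
from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ami, periodicity, records, rei, scan
from .errors import ValidationError

log = logging.getLogger("amirei")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults are the standard analysis settings."""

    alphas: tuple[int, ...] = ami.DEFAULT_ALPHA_NAMES
    rei_numerator: int = rei.DEFAULT_NUMERATOR
    rei_denominator: int = rei.DEFAULT_DENOMINATOR
    rei_threshold: float = rei.DEFAULT_REI_THRESHOLD
    rei_cap: float = rei.DEFAULT_REI_CAP
    bac_threshold: float = 0.05
    min_event_length: int = 1
    bin_width: int = periodicity.DEFAULT_BIN_WIDTH
    max_treatment_day: int = periodicity.DEFAULT_MAX_TREATMENT_DAY
    schedule: int | None = None
    grid_start: float = 0.05
    grid_stop: float = 1.1
    grid_n: int = 17
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.rei_numerator not in self.alphas or self.rei_denominator not in self.alphas:
            raise ValidationError("REI numerator/denominator must be among the alphas")
        if self.rei_threshold <= 0:
            raise ValidationError("rei_threshold must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides (e.g. CLI flags) win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("alphas",):
            if key in raw:
                raw[key] = tuple(raw[key])
        raw.update(overrides)
        cfg = cls(**raw)
        for f in fields(cfg):
            log.info("config %s = %r", f.name, getattr(cfg, f.name))
        return cfg

    def ami_params(self) -> ami.AmiParams:
        return ami.AmiParams(bac_threshold=self.bac_threshold)

    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_start, self.grid_stop, self.grid_n)


def compute_rei_table(ami_table: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Per-day REI for every patient, aligned with the AMI table."""
    num, den = f"ami_{config.rei_numerator}", f"ami_{config.rei_denominator}"
    out = ami_table[["patient_id", "date", "treatment_day"]].copy()
    out["rei"] = np.nan
    for pid, grp in ami_table.groupby("patient_id", sort=False):
        out.loc[grp.index, "rei"] = rei.compute_rei(
            grp[num].to_numpy(), grp[den].to_numpy(), cap=config.rei_cap
        )
    return out


def detect_cohort_events(rei_table: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Exacerbation events for every patient, as one table."""
    frames = []
    for pid, grp in rei_table.groupby("patient_id", sort=False):
        events = rei.detect_events(grp["rei"].to_numpy(), config.rei_threshold)
        frame = rei.events_to_frame(events, pid, dates=grp["date"].tolist())
        if not frame.empty:
            frames.append(frame)
    if not frames:
        return rei.events_to_frame([], "", [])
    return pd.concat(frames, ignore_index=True)


def summarize_cohort(
    days: pd.DataFrame,
    ami_table: pd.DataFrame,
    rei_table: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    rows = []
    for pid, grp in days.groupby("patient_id", sort=False):
        events = rei.detect_events(
            rei_table.loc[grp.index, "rei"].to_numpy(), config.rei_threshold
        )
        ami21 = (
            ami_table.loc[grp.index, "ami_21"].to_numpy()
            if "ami_21" in ami_table.columns
            else None
        )
        s = rei.summarize_patient(grp, ami21, events, config.min_event_length)
        rows.append(vars(s))
    return pd.DataFrame(rows)


def run_pipeline(
    tests: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every analysis stage on a test log; optionally write the CSV bundle.

    Returns a dict of tables: ``days``, ``ami``, ``rei``, ``events``,
    ``summary``, ``cohort_days`` and ``periodicity_<factor>`` for weekday,
    ISO week and treatment bin.  Deterministic for fixed inputs and config.
    """
    days = records.aggregate_days(
        tests, schedule=config.schedule, params=config.ami_params(), covariates=covariates
    )
    log.info("day table: %d rows, %d patients", len(days), days["patient_id"].nunique())
    ami_table = ami.compute_ami_family(days, config.alphas)
    rei_table = compute_rei_table(ami_table, config)
    events = detect_cohort_events(rei_table, config)
    log.info("events: %d", len(events))
    summary = summarize_cohort(days, ami_table, rei_table, config)
    cohort = periodicity.build_cohort_table(
        days,
        (rei_table["rei"] < config.rei_threshold).to_numpy(),
        bin_width=config.bin_width,
        max_treatment_day=config.max_treatment_day,
    )
    bundle: dict[str, pd.DataFrame] = {
        "days": days,
        "ami": ami_table,
        "rei": rei_table,
        "events": events,
        "summary": summary,
        "cohort_days": cohort,
    }
    for factor in periodicity.FACTORS:
        bundle[f"periodicity_{factor}"] = periodicity.percent_ee_by(cohort, factor)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            log.info("wrote %s (%d rows)", path, len(df))
    return bundle


def scan_bundle(bundle: dict[str, pd.DataFrame], config: RunConfig) -> scan.ScanResult:
    """Threshold scan on a pipeline bundle, joining REI with the DDD covariate."""
    merged = bundle["rei"].merge(
        bundle["days"][["patient_id", "date", "ddd"]], on=["patient_id", "date"]
    )
    return scan.scan_thresholds(merged, grid=config.grid())
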