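import pandas as pd
import pytest

from amirei import RunConfig, run_pipeline, simulate_cohort


def make_log(rows):
    """Build a test-log DataFrame from (pid, start, end, performed, brac) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "window_start",
            "window_end",
            "performed_at",
            "brac_permille",
        ],
    ).assign(
        window_start=lambda d: pd.to_datetime(d["window_start"]),
        window_end=lambda d: pd.to_datetime(d["window_end"]),
        performed_at=lambda d: pd.to_datetime(d["performed_at"]),
    )


@pytest.fixture(scope="session")
def cohort():
    """A small mixed-behaviour cohort with covariates: (tests, truth)."""
    return simulate_cohort(
        8, {"weekend_binger": 0.5, "periodic_heavy": 0.25, "controlled": 0.25},
        seed=7, n_days=120,
    )


@pytest.fixture(scope="session")
def bundle(cohort):
    tests, truth = cohort
    cov = truth[["patient_id", "date", "ddd", "peth_umol_l"]]
    return run_pipeline(tests, covariates=cov, config=RunConfig())
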