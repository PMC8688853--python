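# amirei

Digital biomarkers for breathalyzer-based monitoring of alcohol use disorder
(AUD).

Patients in eHealth-supported AUD treatment perform 2–5 scheduled breathalyzer
tests per day; a test skipped within its window is an *omission*. `amirei`
turns these logs into continuous descriptions of the clinical course:

- **AMI** (Addiction Monitoring Index): a 0–100 sobriety/compliance index.
  Each test scores 1 (performed, blood alcohol content BAC < 0.05 ‰), 0
  (performed, BAC ≥ 0.05 ‰), or an imputed value that decays linearly over an
  omission streak, reaching 0 after 48 h of silence (BAC = 2.0 × breath
  alcohol; the 0.05 ‰ threshold comes from the measurement level of
  quantification, median + 10·IQR = 0.046 ‰). The daily mean score x_t is
  exponentially smoothed, s_0 = x_0, s_t = α·x_t + (1−α)·s_{t−1}; AMI-N uses
  α = N/100.
- **REI** (Recovery and Exacerbation Index): the ratio AMI-45 / AMI-6 of a
  short-memory to a long-memory index. REI < 1 means the patient is doing
  worse short-term than their own baseline, independent of the absolute level.
- **EE** (exacerbation event): a maximal run of consecutive days with
  REI < 0.8 — a measurement-based replacement for the binary lapse/relapse
  concept, summarised per patient as %EE, event count, mean/max length and
  time between events.

Around the core indices the package provides: per-day aggregation with
maximum-time-between-tests (MTBT) compliance tracking, an ANOVA scan that
selects the REI threshold by maximising the F-ratio of drinks-per-drinking-day
(DDD) between in- and out-of-event days, cohort periodicity analysis (%EE by
weekday, ISO week and treatment-day bin with patient-clustered logistic
tests), a synthetic-cohort simulator with known ground truth, plotting, and a
CLI.

## Worked example

```python
from amirei import (RunConfig, run_pipeline, scan_bundle, select_threshold,
                    simulate_cohort)

tests, truth = simulate_cohort(10, "weekend_binger", seed=1, n_days=120)
cov = truth[["patient_id", "date", "ddd", "peth_umol_l"]]
bundle = run_pipeline(tests, covariates=cov, config=RunConfig())

print(bundle["summary"][["patient_id", "percent_ee", "ee_count",
                         "mean_ee_length", "ami21_mean"]].head(3))
choice = select_threshold(scan_bundle(bundle, RunConfig()))
print(f"scan-recommended threshold: {choice.threshold:.3f}")
```

prints

```
  patient_id  percent_ee  ee_count  mean_ee_length  ami21_mean
0      P0001    6.666667         5        1.600000   89.104247
1      P0002    7.500000         6        1.500000   92.986135
2      P0003    6.666667         7        1.142857   93.433897
scan-recommended threshold: 0.969
```

Patient P0001 spent 6.7% of monitored days inside five exacerbation events of
mean length 1.6 days, with a mean AMI-21 of 89 — short weekend episodes
against a high-compliance baseline; the threshold scan on this small cohort
recommends an REI cut-off at the upper end of its high-F plateau.

The same pipeline is available from the shell:

```bash
amirei simulate --n-patients 10 --archetype weekend_binger --seed 1 --outdir out
amirei all out/tests.csv --covariates out/truth.csv --outdir out
amirei scan out/tests.csv --covariates out/truth.csv --outdir out
amirei plot out/tests.csv --patient P0001 --outdir out
```

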