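"""Clinical-course plots: multi-panel per-patient figures.

The layout mirrors what a therapist-facing monitoring view shows: the AMI-21
trajectory with exacerbation-event days highlighted in red, the REI with its
threshold line, and raw panels for MaxBAC, omitted tests, MTBT, plus the DDD
and PEth covariates when present.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .errors import ValidationError
from .rei import DEFAULT_REI_THRESHOLD


def render_course(
    bundle: dict[str, pd.DataFrame],
    patient_id: str,
    path: str | Path,
    threshold: float = DEFAULT_REI_THRESHOLD,
) -> Path:
    """Render one patient's clinical course to an image file."""
    days = bundle["days"][bundle["days"]["patient_id"] == patient_id]
    if days.empty:
        raise ValidationError(f"unknown patient {patient_id!r}")
    ami = bundle["ami"][bundle["ami"]["patient_id"] == patient_id]
    rei = bundle["rei"][bundle["rei"]["patient_id"] == patient_id]
    events = bundle["events"][bundle["events"]["patient_id"] == patient_id]

    panels = ["ami", "rei", "max_bac", "omissions", "mtbt"]
    if days["ddd"].notna().any():
        panels.append("ddd")
    if days["peth_umol_l"].notna().any():
        panels.append("peth")
    fig, axes = plt.subplots(
        len(panels), 1, figsize=(10, 1.8 * len(panels)), sharex=True
    )
    t = days["treatment_day"].to_numpy()

    ax = axes[0]
    ax.plot(t, ami["ami_21"], color="black", lw=1)
    for _, ev in events.iterrows():
        span = (t >= ev["start_day"]) & (t <= ev["end_day"])
        ax.plot(t[span], ami["ami_21"].to_numpy()[span], color="red", lw=2)
    ax.set_ylabel("AMI-21")
    ax.set_ylim(0, 105)

    ax = axes[1]
    ax.plot(t, rei["rei"], color="tab:blue", lw=1)
    ax.axhline(threshold, color="red", lw=1)
    ax.set_ylabel("REI")

    axes[2].plot(t, days["max_bac_permille"], ".", ms=3, color="tab:purple")
    axes[2].set_ylabel("MaxBAC (‰)")
    axes[3].bar(t, days["n_omitted"], width=1, color="gray")
    axes[3].set_ylabel("omitted")
    axes[4].plot(t, days["mtbt_hours"], color="tab:orange", lw=1)
    axes[4].set_ylabel("MTBT (h)")

    idx = 5
    if "ddd" in panels:
        axes[idx].plot(t, days["ddd"], ".", ms=3, color="tab:green")
        axes[idx].set_ylabel("DDD")
        idx += 1
    if "peth" in panels:
        axes[idx].plot(t, days["peth_umol_l"], color="tab:red", lw=1)
        axes[idx].axhline(0.3, color="red", lw=0.5, ls="--")
        axes[idx].set_ylabel("PEth")

    axes[-1].set_xlabel("treatment day")
    fig.suptitle(f"Patient {patient_id}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
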