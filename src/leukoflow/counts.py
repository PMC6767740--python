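"""Differential counts: per-donor WBC percentages vs clinical reference ranges.

Turns per-cell class predictions into the clinical readout: the percentage
of each WBC type per donor, the unweighted cohort mean and SD per class,
and a comparison of each cohort mean against its (closed) reference
interval — lymphocytes 20-40%, eosinophils 1-6%, monocytes 2-10%,
neutrophils 40-80%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .presets import REFERENCE_RANGES_PCT, STAGE1_CLASSES

__all__ = ["DifferentialCount", "differential_count", "compare_to_reference"]


@dataclass
class DifferentialCount:
    """Per-donor and cohort-average WBC percentages."""

    per_donor: pd.DataFrame  # index: donor_id, columns: classes, values: %
    cohort_mean: pd.Series  # unweighted mean over donors, %
    cohort_sd: pd.Series
    reference_ranges: dict[str, tuple[float, float]]
    in_range: dict[str, bool] = field(default_factory=dict)
    per_donor_stage2: pd.DataFrame | None = None  # optional B/T % of lymphocytes


def differential_count(
    predictions: pd.DataFrame,
    *,
    classes=STAGE1_CLASSES,
    reference_ranges: dict[str, tuple[float, float]] | None = None,
) -> DifferentialCount:
    """Differential count from per-cell predictions grouped by donor.

    ``predictions`` needs columns ``donor_id`` and ``predicted_stage1``
    (optionally ``predicted_stage2`` for the B/T split of lymphocytes).
    Per-donor percentages are over that donor's classified cells and sum
    to 100; the cohort mean is the unweighted mean over donors. Donors
    without classified cells are excluded with a warning.
    """
    ranges = REFERENCE_RANGES_PCT if reference_ranges is None else reference_ranges
    required = {"donor_id", "predicted_stage1"}
    if not required.issubset(predictions.columns):
        raise ValueError(f"predictions must have columns {sorted(required)}")
    if predictions.empty:
        raise ValueError("no predictions to count")

    rows = {}
    stage2_rows = {}
    for donor, grp in predictions.groupby("donor_id", sort=True):
        grp = grp[grp["predicted_stage1"].isin(classes)]
        if grp.empty:
            warnings.warn(f"donor {donor}: no classified cells; excluded", stacklevel=2)
            continue
        frac = grp["predicted_stage1"].value_counts(normalize=True)
        rows[donor] = {cls: 100.0 * float(frac.get(cls, 0.0)) for cls in classes}
        if "predicted_stage2" in grp.columns:
            lymph = grp[grp["predicted_stage1"] == "lymphocyte"]
            lymph = lymph[lymph["predicted_stage2"].isin(("B", "T"))]
            if not lymph.empty:
                bt = lymph["predicted_stage2"].value_counts(normalize=True)
                stage2_rows[donor] = {
                    "B": 100.0 * float(bt.get("B", 0.0)),
                    "T": 100.0 * float(bt.get("T", 0.0)),
                }
    if not rows:
        raise ValueError("no donor had classified cells")

    per_donor = pd.DataFrame.from_dict(rows, orient="index")[list(classes)]
    per_donor.index.name = "donor_id"
    cohort_mean = per_donor.mean(axis=0)
    cohort_sd = per_donor.std(axis=0, ddof=0)
    count = DifferentialCount(
        per_donor=per_donor,
        cohort_mean=cohort_mean,
        cohort_sd=cohort_sd,
        reference_ranges=ranges,
        per_donor_stage2=pd.DataFrame.from_dict(stage2_rows, orient="index")
        if stage2_rows
        else None,
    )
    report = compare_to_reference(count, ranges)
    count.in_range = {cls: bool(report.loc[cls, "in_range"]) for cls in report.index}
    return count


def compare_to_reference(
    count: DifferentialCount | pd.Series,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-class in/out-of-range report for cohort-average percentages.

    Intervals are closed (a boundary value counts as in range); outside
    values report their signed deviation from the nearest bound.
    """
    ranges = REFERENCE_RANGES_PCT if ranges is None else ranges
    means = count.cohort_mean if isinstance(count, DifferentialCount) else count
    missing = [cls for cls in means.index if cls not in ranges]
    if missing:
        raise KeyError(f"classes missing from reference ranges: {missing}")
    rows = {}
    for cls in means.index:
        lo, hi = ranges[cls]
        value = float(means[cls])
        if value < lo:
            deviation = value - lo
        elif value > hi:
            deviation = value - hi
        else:
            deviation = 0.0
        rows[cls] = {
            "value": value,
            "low": lo,
            "high": hi,
            "in_range": lo <= value <= hi,
            "deviation": deviation,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def plot_reference_comparison(count: DifferentialCount, path=None):
    """Bar chart of cohort mean ± SD against the reference intervals."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = list(count.per_donor.columns)
    x = np.arange(len(classes))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(x, count.cohort_mean[classes], yerr=count.cohort_sd[classes], capsize=4,
           color="#5b8bd0", label="cohort mean ± SD")
    for i, cls in enumerate(classes):
        lo, hi = count.reference_ranges[cls]
        ax.plot([i - 0.3, i + 0.3], [lo, lo], color="k", lw=1)
        ax.plot([i - 0.3, i + 0.3], [hi, hi], color="k", lw=1)
        ax.plot([i, i], [lo, hi], color="k", lw=0.5, ls=":")
    ax.set_xticks(x, classes, rotation=20)
    ax.set_ylabel("% of WBC")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
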