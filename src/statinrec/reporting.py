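"""Reporting surfaces: recommendation-group profiles and per-patient reports.

Two views of a fitted recommender's output: (i) a cohort-level table
summarizing the baseline characteristics of each recommendation group
(mean +/- SD for continuous variables, n (%) for binary/categorical ones,
plus the group's mean predicted reduction under the recommended arm), and
(ii) a per-patient structure carrying the four predicted reductions, the
recommended arm and selected baseline characteristics, with an optional bar
chart rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .defaults import ARMS, INTENSITY_ORDER

__all__ = [
    "GroupProfile",
    "profile_groups",
    "profiles_to_frame",
    "patient_report",
    "render_patient_report",
    "DEFAULT_PROFILE_CONTINUOUS",
    "DEFAULT_PROFILE_BINARY",
]

DEFAULT_PROFILE_CONTINUOUS = (
    "age",
    "baseline_ldl",
    "sbp",
    "n_meds_prior_year",
    "n_primary_care_visits",
    "median_income",
    "pct_bachelors",
)
DEFAULT_PROFILE_BINARY = ("smoker", "diabetes", "antihypertensive")
DEFAULT_PROFILE_CATEGORICAL = ("sex", "race")


@dataclass
class GroupProfile:
    """Summary of the patients recommended one arm."""

    arm: str
    n: int
    continuous: dict[str, tuple[float, float | None]]  # name -> (mean, sd)
    binary: dict[str, tuple[int, float]]  # name -> (count, percent)
    categorical: dict[str, dict[str, tuple[int, float]]]
    mean_predicted_reduction: float


def profile_groups(
    recommendations: pd.DataFrame,
    cohort: pd.DataFrame,
    continuous: tuple[str, ...] = DEFAULT_PROFILE_CONTINUOUS,
    binary: tuple[str, ...] = DEFAULT_PROFILE_BINARY,
    categorical: tuple[str, ...] = DEFAULT_PROFILE_CATEGORICAL,
) -> list[GroupProfile]:
    """One profile per arm that received at least one recommendation.

    Summaries use raw (unstandardized) covariates; the mean predicted
    reduction averages each member's estimate under their recommended arm.
    SD is reported as None for single-patient groups.
    """
    merged = recommendations.merge(cohort, on="patient_id", how="left", validate="1:1")
    profiles = []
    for arm in sorted(
        merged["recommended_arm"].unique(), key=lambda a: INTENSITY_ORDER[a]
    ):
        grp = merged[merged["recommended_arm"] == arm]
        cont = {}
        for name in continuous:
            if name not in grp.columns:
                continue
            vals = grp[name].astype(float)
            sd = float(vals.std(ddof=1)) if len(grp) > 1 else None
            cont[name] = (float(vals.mean()), sd)
        binr = {}
        for name in binary:
            if name not in grp.columns:
                continue
            count = int(grp[name].fillna(0).astype(float).round().sum())
            binr[name] = (count, 100.0 * count / len(grp))
        catg = {}
        for name in categorical:
            if name not in grp.columns:
                continue
            counts = grp[name].value_counts()
            catg[name] = {
                str(lv): (int(c), 100.0 * int(c) / len(grp))
                for lv, c in counts.items()
            }
        profiles.append(
            GroupProfile(
                arm=arm,
                n=len(grp),
                continuous=cont,
                binary=binr,
                categorical=catg,
                mean_predicted_reduction=float(grp[f"yhat_{arm}"].mean()),
            )
        )
    return profiles


def profiles_to_frame(profiles: list[GroupProfile]) -> pd.DataFrame:
    """Long-format table: one row per (group, variable, statistic)."""
    rows = []
    for p in profiles:
        rows.append(
            {"arm": p.arm, "variable": "n", "statistic": "count", "value": p.n}
        )
        rows.append(
            {
                "arm": p.arm,
                "variable": "predicted_reduction_recommended",
                "statistic": "mean",
                "value": p.mean_predicted_reduction,
            }
        )
        for name, (mean, sd) in p.continuous.items():
            rows.append({"arm": p.arm, "variable": name, "statistic": "mean",
                         "value": mean})
            if sd is not None:
                rows.append({"arm": p.arm, "variable": name, "statistic": "sd",
                             "value": sd})
        for name, (count, pct) in p.binary.items():
            rows.append({"arm": p.arm, "variable": name, "statistic": "count",
                         "value": count})
            rows.append({"arm": p.arm, "variable": name, "statistic": "percent",
                         "value": pct})
        for name, levels in p.categorical.items():
            for lv, (count, pct) in levels.items():
                rows.append({"arm": p.arm, "variable": f"{name}={lv}",
                             "statistic": "count", "value": count})
                rows.append({"arm": p.arm, "variable": f"{name}={lv}",
                             "statistic": "percent", "value": pct})
    return pd.DataFrame(rows)


def patient_report(recommendation_row: pd.Series, cohort_row: pd.Series) -> dict:
    """Render-ready per-patient structure: the four predicted reductions,
    the recommended arm, and selected baseline characteristics."""
    report = {
        "patient_id": str(recommendation_row["patient_id"]),
        "predicted_reduction_pct": {
            arm: float(recommendation_row[f"yhat_{arm}"]) for arm in ARMS
        },
        "recommended_arm": str(recommendation_row["recommended_arm"]),
        "tie": bool(recommendation_row.get("tie_flag", False)),
        "characteristics": {
            "age": float(cohort_row["age"]),
            "sex": str(cohort_row["sex"]),
            "baseline_ldl": float(cohort_row["baseline_ldl"]),
            "diabetes": int(cohort_row.get("diabetes", 0)),
            "smoker": int(cohort_row.get("smoker", 0)),
        },
    }
    # guard: serializable and self-consistent
    json.dumps(report)
    assert report["predicted_reduction_pct"][report["recommended_arm"]] >= (
        max(report["predicted_reduction_pct"].values()) - 1e-9
    )
    return report


def render_patient_report(report: dict, path: str | Path) -> None:
    """Bar chart of the four predicted reductions, recommended arm accented."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    vals = [report["predicted_reduction_pct"][a] for a in ARMS]
    colors = [
        "#d62728" if a == report["recommended_arm"] else "#7f7f7f" for a in ARMS
    ]
    ax.bar(ARMS, vals, color=colors)
    ax.set_ylabel("Predicted 1-yr LDL-C reduction (%)")
    ax.set_title(
        f"Patient {report['patient_id']}: recommended "
        f"{report['recommended_arm']}-intensity"
        if report["recommended_arm"] != "none"
        else f"Patient {report['patient_id']}: no statin recommended"
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
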