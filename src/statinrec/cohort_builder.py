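"""Eligibility filtering, index-date resolution, arm assignment and outcome.

Turns a raw longitudinal EHR extract into one analysis row per eligible
patient.  Filters are applied in a fixed order and every exclusion is tallied,
so that ``n_input == n_output + sum(exclusions)`` always holds (a CONSORT-style
accounting).  The outcome is the relative percent reduction in LDL-C at 1-year
follow-up:

    y = 100 * (baseline_ldl - followup_ldl) / baseline_ldl

with the baseline taken as the most recent LDL-C on or before the index date
and the follow-up as the LDL-C closest to index + 365 days within a symmetric
window (ties broken toward the earlier date).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .defaults import (
    ANTIHYPERTENSIVE_AGENTS,
    DEFAULT_CVD_EXCLUSION_CODES,
    DEFAULT_STATIN_INTENSITY_MAP,
    DIABETES_AGENTS,
    KNOWN_STATIN_AGENTS,
)
from .errors import ConfigurationError
from .synthetic_cohort import EHRTables

__all__ = [
    "EligibilityConfig",
    "build_cohort",
    "resolve_index_date",
    "assign_arm",
    "compute_outcome",
    "statin_intensity",
]

CHOLESTEROL_CODES = ("LDL", "TC", "HDL")

#: filter order; tallies are emitted in this order
FILTER_ORDER = (
    "insufficient_visits",
    "age_out_of_range",
    "prior_cvd",
    "no_cholesterol_lab",
    "missing_baseline_data",
    "prior_statin",
    "unstable_statin_intensity",
    "no_followup_ldl",
)


@dataclass
class EligibilityConfig:
    age_min: float = 40.0
    age_max: float = 79.0
    cvd_exclusion_codes: tuple[str, ...] = DEFAULT_CVD_EXCLUSION_CODES
    outcome_target_days: int = 365
    outcome_window_days: int = 183
    intensity_map: dict = field(
        default_factory=lambda: dict(DEFAULT_STATIN_INTENSITY_MAP)
    )
    split_date: pd.Timestamp = pd.Timestamp("2015-01-01")
    lookback_days: int = 365
    min_visit_gap_days: int = 365

    def __post_init__(self) -> None:
        if not self.age_min < self.age_max:
            raise ConfigurationError("age_min must be < age_max")
        if not self.outcome_window_days < self.outcome_target_days:
            raise ConfigurationError(
                "outcome_window_days must be < outcome_target_days"
            )
        self.split_date = pd.Timestamp(self.split_date)


def statin_intensity(agent: str, dose_mg: float, intensity_map: dict) -> str | None:
    """Map an (agent, daily dose) to its intensity category.

    Returns ``None`` for agents that are not statins.  Raises
    :class:`ConfigurationError` for a statin agent missing from the map or a
    dose outside every configured range.
    """
    if agent not in intensity_map:
        if agent in KNOWN_STATIN_AGENTS:
            raise ConfigurationError(
                f"statin agent '{agent}' is absent from the intensity map"
            )
        return None
    for lo, hi, intensity in intensity_map[agent]:
        if lo <= dose_mg <= hi:
            return intensity
    raise ConfigurationError(
        f"dose {dose_mg} mg of '{agent}' is not covered by the intensity map"
    )


def resolve_index_date(
    nominal_index: pd.Timestamp, patient_labs: pd.DataFrame
) -> pd.Timestamp | None:
    """Shift the index date forward to the first cholesterol result if needed.

    Returns the nominal index date when a cholesterol result (LDL-C, total
    cholesterol or HDL-C) exists on or before it, otherwise the date of the
    first cholesterol result; ``None`` when the patient has no cholesterol
    results at all (ineligible, not an error).
    """
    chol = patient_labs[patient_labs["test_code"].isin(CHOLESTEROL_CODES)]
    if chol.empty:
        return None
    first = chol["date"].min()
    return nominal_index if first <= nominal_index else first


def assign_arm(
    patient_rx: pd.DataFrame, index_date: pd.Timestamp, config: EligibilityConfig
) -> str | None:
    """Assign the statin decision, or ``None`` for an ineligible patient.

    A statin prescribed on or before the index date marks prior statin use
    (ineligible).  With no statin in the follow-up year the arm is ``none``;
    a single follow-up intensity category gives that arm; a category change
    during follow-up marks the patient unstable (ineligible).
    """
    intensities = []
    horizon = index_date + pd.Timedelta(days=config.outcome_target_days)
    for row in patient_rx.itertuples():
        cat = statin_intensity(row.agent, row.dose_mg, config.intensity_map)
        if cat is None:
            continue
        if row.start_date <= index_date:
            return None  # prior statin use
        if row.start_date <= horizon:
            intensities.append(cat)
    if not intensities:
        return "none"
    unique = set(intensities)
    if len(unique) > 1:
        return None  # unstable intensity during follow-up
    return unique.pop()


def compute_outcome(
    patient_labs: pd.DataFrame, index_date: pd.Timestamp, config: EligibilityConfig
) -> tuple[float, float, float] | None:
    """Return (baseline_ldl, followup_ldl, outcome_pct), or ``None``.

    Baseline is the most recent LDL-C on or before the index date; follow-up
    is the LDL-C dated closest to index + ``outcome_target_days`` among those
    within +/- ``outcome_window_days`` (ties go to the earlier date).
    """
    ldl = patient_labs[patient_labs["test_code"] == "LDL"]
    base = ldl[ldl["date"] <= index_date]
    if base.empty:
        return None
    baseline = float(base.sort_values("date", kind="mergesort").iloc[-1]["value"])
    target = index_date + pd.Timedelta(days=config.outcome_target_days)
    lo = target - pd.Timedelta(days=config.outcome_window_days)
    hi = target + pd.Timedelta(days=config.outcome_window_days)
    cand = ldl[(ldl["date"] >= lo) & (ldl["date"] <= hi)].copy()
    if cand.empty:
        return None
    cand["gap"] = (cand["date"] - target).abs()
    cand = cand.sort_values(["gap", "date"], kind="mergesort")
    followup = float(cand.iloc[0]["value"])
    outcome = 100.0 * (baseline - followup) / baseline
    return baseline, followup, outcome


def _code_hits(codes: pd.Series, exclusion: tuple[str, ...]) -> pd.Series:
    exact = {c for c in exclusion if not c.endswith("*")}
    prefixes = tuple(c[:-1] for c in exclusion if c.endswith("*"))
    hit = codes.isin(exact)
    if prefixes:
        hit |= codes.str.startswith(prefixes)
    return hit


def _code_excluded(codes: pd.Series, exclusion: tuple[str, ...]) -> bool:
    return bool(_code_hits(codes, exclusion).any())


def build_cohort(
    tables: EHRTables, config: EligibilityConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply all eligibility rules and return (cohort table, exclusion tally).

    The cohort table carries the raw covariates the feature stage needs:
    demographics, most-recent labs/vitals, lookback condition flags,
    utilization counts and socioeconomic indicators, plus ``arm``,
    ``baseline_ldl``, ``followup_ldl``, ``outcome_pct`` and the temporal
    ``split`` (train iff index_date < split_date).
    """
    config = config or EligibilityConfig()
    tally = {name: 0 for name in FILTER_ORDER}
    empty = pd.DataFrame(
        columns=["patient_id", "index_date", "arm", "baseline_ldl",
                 "followup_ldl", "outcome_pct", "split"]
    )

    pts = tables.patients.set_index("patient_id", drop=False)
    pts.index.name = None  # keep 'patient_id' unambiguous in later merges

    def drop(keep: pd.Series, reason: str) -> None:
        tally[reason] += int((~keep).sum())

    # 1. enrollment: at least two visits spanning the minimum gap
    span = tables.visits.groupby("patient_id")["date"].agg(["min", "max", "size"])
    span = span.reindex(pts.index)
    keep = (span["size"].fillna(0) >= 2) & (
        (span["max"] - span["min"]).dt.days >= config.min_visit_gap_days
    )
    drop(keep, "insufficient_visits")
    pts = pts[keep]
    if pts.empty:
        return empty, tally

    # index-date resolution (needed by the age probe; the no-lab exclusion
    # itself is tallied later, in filter order)
    chol = tables.labs[tables.labs["test_code"].isin(CHOLESTEROL_CODES)]
    first_chol = chol.groupby("patient_id")["date"].min().reindex(pts.index)
    resolved = pts["index_date"].where(
        first_chol.isna() | (first_chol <= pts["index_date"]), first_chol
    )

    # 2. age at the (possibly shifted) index date
    probe = resolved.where(first_chol.notna(), pts["index_date"])
    age = np.floor((probe - pts["birth_date"]).dt.days / 365.25)
    keep = (age >= config.age_min) & (age <= config.age_max)
    drop(keep, "age_out_of_range")
    pts, resolved, age = pts[keep], resolved[keep], age[keep]
    first_chol = first_chol[keep]

    # 3. prior cardiovascular disease anywhere in the record
    dx = tables.diagnoses
    cvd_pids = set(dx.loc[_code_hits(dx["code"].astype(str),
                                     config.cvd_exclusion_codes), "patient_id"])
    keep = ~pts.index.isin(cvd_pids)
    drop(pd.Series(keep, index=pts.index), "prior_cvd")
    pts, resolved, age = pts[keep], resolved[keep], age[keep]
    first_chol = first_chol[keep]

    # 4. at least one cholesterol result (otherwise no index can be fixed)
    keep = first_chol.notna()
    drop(keep, "no_cholesterol_lab")
    pts, resolved, age = pts[keep], resolved[keep], age[keep]
    if pts.empty:
        return empty, tally

    # 5. baseline data: most recent value on/before index per test code
    labs = tables.labs.merge(
        resolved.rename("idx"), left_on="patient_id", right_index=True
    )
    base = labs[labs["date"] <= labs["idx"]]
    base = base.sort_values("date", kind="mergesort")
    wide = base.groupby(["patient_id", "test_code"])["value"].last().unstack()
    wide = wide.reindex(pts.index)
    for code in ("TC", "HDL", "SBP", "DBP", "HEIGHT", "WEIGHT", "LDL"):
        if code not in wide.columns:
            wide[code] = np.nan
    keep = wide[["TC", "HDL", "SBP"]].notna().all(axis=1)
    drop(keep, "missing_baseline_data")
    pts, resolved, age, wide = pts[keep], resolved[keep], age[keep], wide[keep]

    # 6. statin exposure: none before index, one stable intensity in follow-up
    rx = tables.prescriptions
    statin_agents = set(config.intensity_map) | KNOWN_STATIN_AGENTS
    srx = rx[rx["agent"].isin(statin_agents)].copy()
    if not srx.empty:
        pairs = srx[["agent", "dose_mg"]].drop_duplicates()
        pairs["intensity"] = [
            statin_intensity(a, d, config.intensity_map)
            for a, d in zip(pairs["agent"], pairs["dose_mg"])
        ]
        srx = srx.merge(pairs, on=["agent", "dose_mg"])
        srx = srx.merge(resolved.rename("idx"), left_on="patient_id",
                        right_index=True)
        prior_pids = set(srx.loc[srx["start_date"] <= srx["idx"], "patient_id"])
        fup = srx[
            (srx["start_date"] > srx["idx"])
            & (
                srx["start_date"]
                <= srx["idx"] + pd.Timedelta(days=config.outcome_target_days)
            )
        ]
        n_cat = fup.groupby("patient_id")["intensity"].nunique()
        arm_of = fup.groupby("patient_id")["intensity"].first()
    else:
        prior_pids = set()
        n_cat = pd.Series(dtype=int)
        arm_of = pd.Series(dtype=object)

    keep = ~pts.index.isin(prior_pids)
    drop(pd.Series(keep, index=pts.index), "prior_statin")
    pts, resolved, age, wide = pts[keep], resolved[keep], age[keep], wide[keep]

    n_cat = n_cat.reindex(pts.index).fillna(0)
    keep = n_cat <= 1
    drop(keep, "unstable_statin_intensity")
    pts, resolved, age, wide = pts[keep], resolved[keep], age[keep], wide[keep]
    arm = arm_of.reindex(pts.index).fillna("none")

    # 7. outcome: baseline LDL-C and a follow-up LDL-C inside the window
    ldl = tables.labs[tables.labs["test_code"] == "LDL"].merge(
        resolved.rename("idx"), left_on="patient_id", right_index=True
    )
    target = ldl["idx"] + pd.Timedelta(days=config.outcome_target_days)
    w = pd.Timedelta(days=config.outcome_window_days)
    cand = ldl[(ldl["date"] >= target - w) & (ldl["date"] <= target + w)].copy()
    cand["gap"] = (cand["date"] - cand["idx"]
                   - pd.Timedelta(days=config.outcome_target_days)).abs()
    cand = cand.sort_values(["gap", "date"], kind="mergesort")
    followup = cand.groupby("patient_id")["value"].first().reindex(pts.index)
    baseline = wide["LDL"]
    keep = followup.notna() & baseline.notna()
    drop(keep, "no_followup_ldl")
    pts, resolved, age, wide = pts[keep], resolved[keep], age[keep], wide[keep]
    arm, baseline, followup = arm[keep], baseline[keep], followup[keep]
    if pts.empty:
        return empty, tally

    # 8. lookback covariates for the survivors
    lb = pd.Timedelta(days=config.lookback_days)
    idx = resolved

    def in_lookback(df: pd.DataFrame, date_col: str) -> pd.DataFrame:
        m = df.merge(idx.rename("idx"), left_on="patient_id", right_index=True)
        return m[(m[date_col] > m["idx"] - lb) & (m[date_col] <= m["idx"])]

    dx_lb = in_lookback(tables.diagnoses, "date")
    dx_lb = dx_lb[dx_lb["code_system"] == "CCS"]
    flag_codes = sorted(
        tables.diagnoses.loc[tables.diagnoses["code_system"] == "CCS", "code"]
        .astype(str)
        .unique()
    )
    flags = (
        pd.crosstab(dx_lb["patient_id"], dx_lb["code"])
        .clip(upper=1)
        .reindex(index=pts.index, columns=flag_codes, fill_value=0)
        .astype(int)
    )
    flags.columns = ["cond_" + str(c).split("_")[-1] for c in flags.columns]

    rx_lb = in_lookback(rx, "start_date")
    n_meds = rx_lb.groupby("patient_id").size().reindex(pts.index).fillna(0)
    labs_lb = in_lookback(tables.labs, "date")
    n_labs = labs_lb.groupby("patient_id").size().reindex(pts.index).fillna(0)
    vis_lb = in_lookback(tables.visits, "date")
    vis_counts = (
        pd.crosstab(vis_lb["patient_id"], vis_lb["visit_type"])
        .reindex(
            index=pts.index,
            columns=["primary_care", "urgent_care", "specialty", "other"],
            fill_value=0,
        )
    )

    rx_before = rx.merge(idx.rename("idx"), left_on="patient_id", right_index=True)
    rx_before = rx_before[rx_before["start_date"] <= rx_before["idx"]]
    antihtn_pids = set(
        rx_before.loc[rx_before["agent"].isin(ANTIHYPERTENSIVE_AGENTS), "patient_id"]
    )
    dm_rx_pids = set(
        rx_before.loc[rx_before["agent"].isin(DIABETES_AGENTS), "patient_id"]
    )
    dx_before = tables.diagnoses.merge(
        idx.rename("idx"), left_on="patient_id", right_index=True
    )
    dm_dx_pids = set(
        dx_before.loc[
            (dx_before["code"] == "CCS_00") & (dx_before["date"] <= dx_before["idx"]),
            "patient_id",
        ]
    )

    socio = tables.socioeconomics.set_index("patient_id").reindex(pts.index)

    cohort = pd.DataFrame(
        {
            "patient_id": pts["patient_id"],
            "index_date": idx,
            "arm": arm,
            "baseline_ldl": baseline.astype(float),
            "followup_ldl": followup.astype(float),
            "outcome_pct": 100.0 * (baseline - followup) / baseline,
            "split": np.where(idx < config.split_date, "train", "test"),
            "age": age.astype(float),
            "sex": pts["sex"],
            "race": pts["race"],
            "smoker": pts["smoker"].astype(int),
            "total_chol": wide["TC"].astype(float),
            "hdl": wide["HDL"].astype(float),
            "sbp": wide["SBP"].astype(float),
            "dbp": wide["DBP"].astype(float),
            "height": wide["HEIGHT"].astype(float),
            "weight": wide["WEIGHT"].astype(float),
            "antihypertensive": pts.index.isin(antihtn_pids).astype(int),
            "n_meds_prior_year": n_meds.astype(int),
            "n_labs_prior_year": n_labs.astype(int),
            "n_primary_care_visits": vis_counts["primary_care"].astype(int),
            "n_urgent_care_visits": vis_counts["urgent_care"].astype(int),
            "n_specialty_visits": vis_counts["specialty"].astype(int),
            "n_other_visits": vis_counts["other"].astype(int),
            "median_income": socio["median_income"].astype(float),
            "pct_bachelors": socio["pct_bachelors"].astype(float),
            "diabetes": (
                pts.index.isin(dm_rx_pids) | pts.index.isin(dm_dx_pids)
            ).astype(int),
        }
    )
    cohort = pd.concat([cohort, flags], axis=1).reset_index(drop=True)
    return cohort, tally
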