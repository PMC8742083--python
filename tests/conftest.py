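"""Shared fixtures: hand-built EHR table fixtures and a small fitted pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from statinrec import (
    CVConfig,
    LassoConfig,
    build_cohort,
    default_schema,
    fit_recommender,
    generate_cohort,
    recommend,
)
from statinrec.scenarios import policy_recovery_config
from statinrec.synthetic_cohort import EHRTables


def eligible_patient_rows(
    pid: str,
    index_date: str = "2014-06-01",
    birth_date: str = "1970-01-15",
    followup_ldl: float = 90.0,
    with_followup: bool = True,
) -> dict[str, list[dict]]:
    """Row dicts for one fully eligible patient (arm 'none', outcome 25%)."""
    idx = pd.Timestamp(index_date)
    rows: dict[str, list[dict]] = {
        "patients": [
            {
                "patient_id": pid,
                "birth_date": pd.Timestamp(birth_date),
                "sex": "F",
                "race": "asian",
                "smoker": 0,
                "index_date": idx,
            }
        ],
        "visits": [
            {"patient_id": pid, "date": idx - pd.Timedelta(days=400),
             "visit_type": "primary_care"},
            {"patient_id": pid, "date": idx, "visit_type": "primary_care"},
        ],
        "labs": [
            {"patient_id": pid, "date": idx - pd.Timedelta(days=12),
             "test_code": "LDL", "value": 120.0, "unit": "mg/dL"},
            {"patient_id": pid, "date": idx - pd.Timedelta(days=12),
             "test_code": "TC", "value": 200.0, "unit": "mg/dL"},
            {"patient_id": pid, "date": idx - pd.Timedelta(days=12),
             "test_code": "HDL", "value": 50.0, "unit": "mg/dL"},
            {"patient_id": pid, "date": idx - pd.Timedelta(days=30),
             "test_code": "SBP", "value": 125.0, "unit": "mmHg"},
            {"patient_id": pid, "date": idx - pd.Timedelta(days=30),
             "test_code": "DBP", "value": 78.0, "unit": "mmHg"},
        ],
        "prescriptions": [],
        "diagnoses": [],
        "visits_extra": [],
        "socioeconomics": [
            {"patient_id": pid, "median_income": 90_000.0, "pct_bachelors": 65.0}
        ],
    }
    if with_followup:
        rows["labs"].append(
            {"patient_id": pid, "date": idx + pd.Timedelta(days=360),
             "test_code": "LDL", "value": followup_ldl, "unit": "mg/dL"}
        )
    rows.pop("visits_extra")
    return rows


def merge_rows(*patients: dict[str, list[dict]]) -> dict[str, list[dict]]:
    merged: dict[str, list[dict]] = {}
    for p in patients:
        for table, rows in p.items():
            merged.setdefault(table, []).extend(rows)
    return merged


def tables_from(*patients: dict[str, list[dict]]) -> EHRTables:
    return EHRTables.from_rows(merge_rows(*patients))


@pytest.fixture(scope="session")
def planted_violation_tables():
    """12 patients: 4 eligible plus one violator of each eligibility rule."""
    clean = [eligible_patient_rows(f"C{i}") for i in range(4)]

    v_visits = eligible_patient_rows("V_VISITS")
    v_visits["visits"] = v_visits["visits"][1:]  # single visit

    v_age = eligible_patient_rows("V_AGE", birth_date="1975-06-01")  # age 39

    v_cvd = eligible_patient_rows("V_CVD")
    v_cvd["diagnoses"].append(
        {"patient_id": "V_CVD", "date": pd.Timestamp("2010-03-01"),
         "code": "I21.0", "code_system": "ICD10"}
    )

    v_nochol = eligible_patient_rows("V_NOCHOL")
    v_nochol["labs"] = [
        r for r in v_nochol["labs"] if r["test_code"] not in ("LDL", "TC", "HDL")
    ]

    v_base = eligible_patient_rows("V_BASE")
    v_base["labs"] = [r for r in v_base["labs"] if r["test_code"] != "HDL"]

    v_prior = eligible_patient_rows("V_PRIOR")
    v_prior["prescriptions"].append(
        {"patient_id": "V_PRIOR", "start_date": pd.Timestamp("2013-01-01"),
         "end_date": pd.Timestamp("2015-01-01"), "agent": "atorvastatin",
         "dose_mg": 10.0}
    )

    v_unstable = eligible_patient_rows("V_UNSTABLE")
    idx = pd.Timestamp("2014-06-01")
    v_unstable["prescriptions"] += [
        {"patient_id": "V_UNSTABLE", "start_date": idx + pd.Timedelta(days=30),
         "end_date": idx + pd.Timedelta(days=150), "agent": "atorvastatin",
         "dose_mg": 10.0},
        {"patient_id": "V_UNSTABLE", "start_date": idx + pd.Timedelta(days=160),
         "end_date": idx + pd.Timedelta(days=400), "agent": "atorvastatin",
         "dose_mg": 80.0},
    ]

    v_nofup = eligible_patient_rows("V_NOFUP", with_followup=False)

    return tables_from(
        *clean, v_visits, v_age, v_cvd, v_nochol, v_base, v_prior,
        v_unstable, v_nofup
    )


@pytest.fixture(scope="session")
def policy_run():
    """One fitted policy-recovery pipeline shared by the slower tests."""
    config = policy_recovery_config(n_patients=7000, seed=11)
    tables, truth = generate_cohort(config)
    cohort, tally = build_cohort(tables)
    train = cohort[cohort["split"] == "train"].reset_index(drop=True)
    test = cohort[cohort["split"] == "test"].reset_index(drop=True).iloc[:1000]
    schema = default_schema()
    models = fit_recommender(train, schema, LassoConfig(), CVConfig(fold_seed=11))
    recs = recommend(test, models, schema)
    return {
        "config": config,
        "truth": truth,
        "cohort": cohort,
        "tally": tally,
        "train": train,
        "test": test,
        "schema": schema,
        "models": models,
        "recommendations": recs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
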