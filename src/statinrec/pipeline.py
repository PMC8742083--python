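"""End-to-end convenience: raw tables -> cohort -> models -> recommendations."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort_builder import EligibilityConfig, build_cohort
from .feature_matrix import FeatureSchema, default_schema
from .metric_learning import LassoConfig
from .reporting import GroupProfile, profile_groups
from .synthetic_cohort import EHRTables
from .wknn_recommender import ArmModel, CVConfig, fit_recommender, recommend

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    exclusions: dict[str, int]
    models: dict[str, ArmModel]
    recommendations: pd.DataFrame
    profiles: list[GroupProfile]


def run_pipeline(
    tables: EHRTables,
    eligibility: EligibilityConfig | None = None,
    schema: FeatureSchema | None = None,
    lasso_config: LassoConfig | None = None,
    cv: CVConfig | None = None,
    max_test_patients: int | None = None,
) -> PipelineResult:
    """Build the cohort, fit the four arm models on the training split and
    recommend a statin decision for every test-split patient.

    ``max_test_patients`` optionally caps the number of scored candidates
    (first rows in patient-id order) to bound runtime on large cohorts.
    """
    schema = schema or default_schema()
    cohort, tally = build_cohort(tables, eligibility)
    train = cohort[cohort["split"] == "train"].reset_index(drop=True)
    test = cohort[cohort["split"] == "test"].reset_index(drop=True)
    if max_test_patients is not None:
        test = test.iloc[:max_test_patients].reset_index(drop=True)
    models = fit_recommender(train, schema, lasso_config, cv)
    recs = recommend(test, models, schema)
    profiles = profile_groups(recs, cohort)
    return PipelineResult(
        cohort=cohort,
        exclusions=tally,
        models=models,
        recommendations=recs,
        profiles=profiles,
    )
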