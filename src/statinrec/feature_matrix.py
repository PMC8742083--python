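"""Per-patient numeric feature assembly and train-referenced standardization.

The feature vector is schema-driven: an ordered list of descriptors maps
cohort-table columns into continuous, count, binary and one-hot-expanded
categorical columns.  Euclidean distances over raw units would be dominated by
large-scale features (income in dollars vs. age in years), so all columns are
standardized with center/scale parameters fit on a stated reference subset —
always the training rows — and reused verbatim elsewhere, which also makes
Lasso coefficient magnitudes comparable as distance weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "FeatureSpec",
    "FeatureSchema",
    "StandardizationParams",
    "default_schema",
    "assemble_features",
    "training_medians",
    "fit_standardizer",
    "apply_standardizer",
    "inverse_standardizer",
]

KINDS = ("continuous", "binary", "count", "categorical")
MISSING_POLICIES = ("impute-train-median", "impute-zero")


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: a cohort column plus how to encode and impute it."""

    name: str
    kind: str = "continuous"
    source: str = "demographic"
    missing_policy: str = "impute-train-median"
    levels: tuple[str, ...] = ()  # categorical only: one-hot expansion order

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"feature '{self.name}': unknown kind '{self.kind}'")
        if self.missing_policy not in MISSING_POLICIES:
            raise SchemaError(
                f"feature '{self.name}': unknown missing policy "
                f"'{self.missing_policy}'"
            )
        if self.kind == "categorical" and not self.levels:
            raise SchemaError(f"feature '{self.name}': categorical needs levels")


@dataclass
class FeatureSchema:
    """Ordered feature list; expanded column order is fixed by the schema."""

    features: list[FeatureSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")

    @property
    def column_names(self) -> list[str]:
        cols: list[str] = []
        for f in self.features:
            if f.kind == "categorical":
                cols.extend(f"{f.name}={lv}" for lv in f.levels)
            else:
                cols.append(f.name)
        return cols


def default_schema(n_condition_flags: int = 20) -> FeatureSchema:
    """The shipped EHR variable set.

    Demographics, the lipid panel and vitals, condition flags, medication and
    laboratory utilization counts, visit counts by type, and census-block
    socioeconomic indicators.  Race is one-hot with an explicit unknown level.
    """
    f = []
    f.append(FeatureSpec("age", "continuous", "demographic"))
    f.append(FeatureSpec("sex", "categorical", "demographic", levels=("F", "M")))
    f.append(
        FeatureSpec(
            "race",
            "categorical",
            "demographic",
            levels=("white", "asian", "hispanic", "black", "other", "unknown"),
        )
    )
    f.append(FeatureSpec("smoker", "binary", "demographic", "impute-zero"))
    for lab in ("baseline_ldl", "total_chol", "hdl"):
        f.append(FeatureSpec(lab, "continuous", "lab"))
    for vital in ("sbp", "dbp", "height", "weight"):
        f.append(FeatureSpec(vital, "continuous", "vital"))
    f.append(FeatureSpec("diabetes", "binary", "condition-flag", "impute-zero"))
    for i in range(n_condition_flags):
        f.append(
            FeatureSpec(f"cond_{i:02d}", "binary", "condition-flag", "impute-zero")
        )
    f.append(FeatureSpec("antihypertensive", "binary", "medication-count", "impute-zero"))
    f.append(FeatureSpec("n_meds_prior_year", "count", "medication-count", "impute-zero"))
    f.append(FeatureSpec("n_labs_prior_year", "count", "lab-utilization", "impute-zero"))
    for v in ("primary_care", "urgent_care", "specialty", "other"):
        f.append(FeatureSpec(f"n_{v}_visits", "count", "visit-count", "impute-zero"))
    f.append(FeatureSpec("median_income", "continuous", "socioeconomic"))
    f.append(FeatureSpec("pct_bachelors", "continuous", "socioeconomic"))
    return FeatureSchema(f)


def training_medians(rows: pd.DataFrame, schema: FeatureSchema) -> dict[str, float]:
    """Per-feature medians for 'impute-train-median' columns, fit on ``rows``."""
    med = {}
    for f in schema.features:
        if f.kind == "categorical" or f.missing_policy != "impute-train-median":
            continue
        if f.name not in rows.columns:
            raise SchemaError(f"feature '{f.name}' not found in cohort columns")
        m = rows[f.name].median()
        med[f.name] = 0.0 if pd.isna(m) else float(m)
    return med


def assemble_features(
    rows: pd.DataFrame,
    schema: FeatureSchema,
    medians: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Build the (n_patients x n_expanded_columns) matrix in schema order.

    ``medians`` must be the training medians when assembling non-training
    rows; when ``None`` they are fit on ``rows`` itself (training use).
    Missing condition flags absent from the cohort table are an error naming
    the feature.
    """
    if medians is None:
        medians = training_medians(rows, schema)
    cols = {}
    for f in schema.features:
        if f.kind == "categorical":
            if f.name not in rows.columns:
                raise SchemaError(f"feature '{f.name}' not found in cohort columns")
            vals = rows[f.name].astype(str)
            for lv in f.levels:
                cols[f"{f.name}={lv}"] = (vals == lv).astype(float).to_numpy()
            continue
        if f.name not in rows.columns:
            # a condition flag never observed in the extract is all-zero,
            # not a schema violation (fixed CCS-style category universe)
            if f.source == "condition-flag" and f.missing_policy == "impute-zero":
                cols[f.name] = np.zeros(len(rows))
                continue
            raise SchemaError(f"feature '{f.name}' not found in cohort columns")
        v = pd.to_numeric(rows[f.name], errors="coerce")
        if f.missing_policy == "impute-zero":
            v = v.fillna(0.0)
        else:
            v = v.fillna(medians.get(f.name, 0.0))
        cols[f.name] = v.to_numpy(dtype=float)
    out = pd.DataFrame(cols, index=rows.index)
    return out[schema.column_names] if cols else pd.DataFrame(index=rows.index)


@dataclass
class StandardizationParams:
    """Per-column center/scale; zero-variance columns get scale 1."""

    columns: list[str]
    center: np.ndarray
    scale: np.ndarray

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, StandardizationParams)
            and self.columns == other.columns
            and np.array_equal(self.center, other.center)
            and np.array_equal(self.scale, other.scale)
        )


def fit_standardizer(
    matrix: pd.DataFrame, reference_rows: np.ndarray | pd.Index | None = None
) -> StandardizationParams:
    """Fit center/scale on ``reference_rows`` (default: all rows of matrix)."""
    ref = matrix if reference_rows is None else matrix.loc[reference_rows]
    if len(ref) == 0:
        raise SchemaError("standardizer reference subset is empty")
    arr = np.ascontiguousarray(ref.to_numpy(dtype=float))
    center = arr.mean(axis=0)
    scale = arr.std(axis=0, ddof=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return StandardizationParams(list(matrix.columns), center, scale)


def apply_standardizer(
    matrix: pd.DataFrame, params: StandardizationParams
) -> pd.DataFrame:
    if list(matrix.columns) != params.columns:
        raise SchemaError("matrix columns do not match standardization parameters")
    return (matrix - params.center) / params.scale


def inverse_standardizer(
    matrix: pd.DataFrame, params: StandardizationParams
) -> pd.DataFrame:
    if list(matrix.columns) != params.columns:
        raise SchemaError("matrix columns do not match standardization parameters")
    return matrix * params.scale + params.center
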