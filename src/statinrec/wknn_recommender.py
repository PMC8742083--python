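"""Per-arm weighted-KNN outcome estimation and argmax treatment choice.

For every candidate patient the model estimates the counterfactual 1-year
relative LDL-C reduction under each of the four statin decisions as the
unweighted mean outcome of the K nearest training patients *within that arm*,
nearest under the arm's Lasso-weighted Euclidean distance.  K is chosen per
arm by fivefold cross-validation among the training patients: in each fold the
metric is refit on the non-held-out folds only (no leakage), held-out patients
of that arm are scored for every candidate K, squared errors are pooled across
folds, and the K minimizing the pooled MSE wins (ties go to the smaller K).
The recommended decision is the arm with the largest estimated reduction; ties
within tolerance go to the lower intensity (least treatment burden under equal
predicted benefit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .defaults import ARMS
from .errors import ConfigurationError
from .feature_matrix import (
    FeatureSchema,
    StandardizationParams,
    apply_standardizer,
    assemble_features,
    fit_standardizer,
    training_medians,
)
from .metric_learning import (
    ArmMetric,
    LassoConfig,
    fit_arm_lasso,
    pairwise_weighted_distances,
)

__all__ = [
    "CVConfig",
    "ArmModel",
    "predict_arm_outcome",
    "select_k",
    "fit_recommender",
    "recommend",
    "save_models",
    "load_models",
]

DEFAULT_K_GRID = (1, 3, 5, 10, 15, 20, 30, 50, 75, 100)


@dataclass
class CVConfig:
    n_folds: int = 5
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    fold_seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(sorted(set(int(k) for k in self.k_grid)))
        if not grid or grid[0] < 1:
            raise ConfigurationError("k_grid must contain positive integers")
        self.k_grid = grid
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")


@dataclass
class ArmModel:
    """A fitted arm: learned metric, selected K, and the matching pool."""

    metric: ArmMetric
    k: int
    cv_mse: dict[int, float]
    pool_ids: np.ndarray
    pool_features: np.ndarray  # standardized, rows aligned with pool_ids
    pool_outcomes: np.ndarray
    standardizer: StandardizationParams
    medians: dict[str, float] = field(default_factory=dict)

    @property
    def arm(self) -> str:
        return self.metric.arm


def _fold_indices(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition into n_folds near-equal folds."""
    order = np.random.default_rng(seed).permutation(n)
    return [fold for fold in np.array_split(order, n_folds)]


def _neighbor_order(distances: np.ndarray, pool_ids: np.ndarray) -> np.ndarray:
    """Ascending by distance, ties broken by ascending patient id."""
    return np.lexsort((pool_ids, distances))


def predict_arm_outcome(
    x: np.ndarray, model: ArmModel, k: int | None = None
) -> tuple[float, list[tuple[str, float]]]:
    """Estimate the reduction for one standardized query under one arm.

    Returns the mean outcome of the K nearest pool patients and the audit
    list of (neighbor id, distance).
    """
    k = model.k if k is None else k
    n_pool = len(model.pool_ids)
    if n_pool == 0:
        raise ConfigurationError(f"arm '{model.arm}' has an empty matching pool")
    if k > n_pool:
        raise ConfigurationError(
            f"K={k} exceeds the arm '{model.arm}' pool size {n_pool}"
        )
    d = pairwise_weighted_distances(np.asarray(x, dtype=float), model.pool_features,
                                    model.metric)[0]
    order = _neighbor_order(d, model.pool_ids)[:k]
    yhat = float(np.mean(model.pool_outcomes[order]))
    neighbors = [(str(model.pool_ids[i]), float(d[i])) for i in order]
    return yhat, neighbors


def _fit_arm_components(
    rows: pd.DataFrame,
    schema: FeatureSchema,
    arm: str,
    lasso_config: LassoConfig,
    seed: int,
):
    medians = training_medians(rows, schema)
    X = assemble_features(rows, schema, medians)
    params = fit_standardizer(X)
    Xs = apply_standardizer(X, params)
    metric = fit_arm_lasso(Xs, rows["outcome_pct"].to_numpy(), arm, lasso_config, seed)
    return medians, params, Xs.to_numpy(dtype=float), metric


def select_k(
    train_rows: pd.DataFrame,
    arm: str,
    schema: FeatureSchema,
    lasso_config: LassoConfig | None = None,
    cv: CVConfig | None = None,
    return_fold_metrics: bool = False,
):
    """Choose K for one arm by fivefold CV with per-fold metric refits.

    Returns ``(K, cv_mse)`` where ``cv_mse[K]`` is the squared error pooled
    over all held-out patients of the arm.  With ``return_fold_metrics`` the
    per-fold :class:`ArmMetric` objects are appended to the return tuple.
    """
    cv = cv or CVConfig()
    lasso_config = lasso_config or LassoConfig()
    arm_rows = train_rows[train_rows["arm"] == arm].reset_index(drop=True)
    n = len(arm_rows)
    if n < cv.n_folds:
        raise ConfigurationError(
            f"arm '{arm}' has {n} training patients, fewer than "
            f"{cv.n_folds} folds"
        )
    folds = _fold_indices(n, cv.n_folds, cv.fold_seed)
    min_pool = min(n - len(f) for f in folds)
    k_grid = [k for k in cv.k_grid if k <= min_pool]
    if not k_grid:
        raise ConfigurationError(
            f"k_grid is empty after truncation to pool size {min_pool}"
        )

    sq_errors: dict[int, list[float]] = {k: [] for k in k_grid}
    fold_metrics = []
    for fold in folds:
        held = arm_rows.iloc[fold]
        fit_rows = arm_rows.drop(index=fold)
        medians, params, pool_X, metric = _fit_arm_components(
            fit_rows, schema, arm, lasso_config, cv.fold_seed
        )
        fold_metrics.append(metric)
        pool_ids = fit_rows["patient_id"].to_numpy()
        pool_y = fit_rows["outcome_pct"].to_numpy()
        Xq = apply_standardizer(
            assemble_features(held, schema, medians), params
        ).to_numpy(dtype=float)
        D = pairwise_weighted_distances(Xq, pool_X, metric)
        y_true = held["outcome_pct"].to_numpy()
        for i in range(len(held)):
            order = _neighbor_order(D[i], pool_ids)
            y_sorted = pool_y[order]
            csum = np.cumsum(y_sorted)
            for k in k_grid:
                yhat = csum[k - 1] / k
                sq_errors[k].append((yhat - y_true[i]) ** 2)

    cv_mse = {k: float(np.mean(v)) for k, v in sq_errors.items()}
    best_k = k_grid[0]
    for k in k_grid[1:]:
        if cv_mse[k] < cv_mse[best_k]:
            best_k = k
    if return_fold_metrics:
        return best_k, cv_mse, fold_metrics
    return best_k, cv_mse


def fit_recommender(
    train_rows: pd.DataFrame,
    schema: FeatureSchema,
    lasso_config: LassoConfig | None = None,
    cv: CVConfig | None = None,
) -> dict[str, ArmModel]:
    """Fit all four arm models on the training cohort.

    Per arm: K by cross-validation, then a final metric refit on all of the
    arm's training patients, whose standardized features and outcomes form
    the matching pool.
    """
    cv = cv or CVConfig()
    lasso_config = lasso_config or LassoConfig()
    present = set(train_rows["arm"].unique())
    missing = [a for a in ARMS if a not in present]
    if missing:
        raise ConfigurationError(
            f"training data is missing arms: {', '.join(missing)}"
        )
    models = {}
    for arm in ARMS:
        best_k, cv_mse = select_k(train_rows, arm, schema, lasso_config, cv)
        arm_rows = train_rows[train_rows["arm"] == arm].reset_index(drop=True)
        medians, params, pool_X, metric = _fit_arm_components(
            arm_rows, schema, arm, lasso_config, cv.fold_seed
        )
        models[arm] = ArmModel(
            metric=metric,
            k=min(best_k, len(arm_rows)),
            cv_mse=cv_mse,
            pool_ids=arm_rows["patient_id"].to_numpy(),
            pool_features=pool_X,
            pool_outcomes=arm_rows["outcome_pct"].to_numpy(),
            standardizer=params,
            medians=medians,
        )
    return models


def recommend(
    test_rows: pd.DataFrame,
    models: dict[str, ArmModel],
    schema: FeatureSchema,
    tie_tol: float = 1e-9,
    audit: bool = False,
):
    """Score all four arms for every candidate and pick the argmax.

    Returns a table with per-arm predicted reductions ``yhat_<arm>``, the
    ``recommended_arm`` and a ``tie_flag``; ties within ``tie_tol`` of the
    maximum are resolved toward the lower intensity.  With ``audit=True`` a
    per-patient mapping of arm -> [(neighbor id, distance), ...] is also
    returned.
    """
    yhats = {}
    audit_data: dict[str, dict[str, list]] = {
        str(p): {} for p in test_rows["patient_id"]
    }
    for arm in ARMS:
        model = models[arm]
        X = assemble_features(test_rows, schema, model.medians)
        Xq = apply_standardizer(X, model.standardizer).to_numpy(dtype=float)
        D = pairwise_weighted_distances(Xq, model.pool_features, model.metric)
        k = model.k
        col = np.empty(len(test_rows))
        for i in range(len(test_rows)):
            order = _neighbor_order(D[i], model.pool_ids)[:k]
            col[i] = np.mean(model.pool_outcomes[order])
            if audit:
                pid = str(test_rows["patient_id"].iloc[i])
                audit_data[pid][arm] = [
                    (str(model.pool_ids[j]), float(D[i][j])) for j in order
                ]
        yhats[arm] = col

    Y = np.column_stack([yhats[a] for a in ARMS])
    max_y = Y.max(axis=1)
    within = Y >= (max_y[:, None] - tie_tol)
    rec_idx = within.argmax(axis=1)  # first (lowest-intensity) arm within tol
    tie_flag = within.sum(axis=1) > 1
    out = pd.DataFrame({"patient_id": test_rows["patient_id"].to_numpy()})
    for a in ARMS:
        out[f"yhat_{a}"] = yhats[a]
    out["recommended_arm"] = np.array(ARMS)[rec_idx]
    out["tie_flag"] = tie_flag
    if audit:
        return out, audit_data
    return out


# --- model bundle persistence (text files only) ------------------------------

def save_models(models: dict[str, ArmModel], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for arm, m in models.items():
        m.metric.to_json(path / f"{arm}_metric.json")
        meta = {
            "k": m.k,
            "cv_mse": {str(k): v for k, v in m.cv_mse.items()},
            "medians": m.medians,
            "standardizer": {
                "columns": m.standardizer.columns,
                "center": m.standardizer.center.tolist(),
                "scale": m.standardizer.scale.tolist(),
            },
        }
        (path / f"{arm}_meta.json").write_text(json.dumps(meta, indent=1))
        pool = pd.DataFrame(
            m.pool_features, columns=m.standardizer.columns
        )
        pool.insert(0, "patient_id", m.pool_ids)
        pool["outcome_pct"] = m.pool_outcomes
        pool.to_csv(path / f"{arm}_pool.csv", index=False)


def load_models(path: str | Path) -> dict[str, ArmModel]:
    path = Path(path)
    models = {}
    for arm in ARMS:
        metric = ArmMetric.from_json(path / f"{arm}_metric.json")
        meta = json.loads((path / f"{arm}_meta.json").read_text())
        pool = pd.read_csv(path / f"{arm}_pool.csv", dtype={"patient_id": str})
        std = meta["standardizer"]
        params = StandardizationParams(
            std["columns"],
            np.array(std["center"], dtype=float),
            np.array(std["scale"], dtype=float),
        )
        models[arm] = ArmModel(
            metric=metric,
            k=int(meta["k"]),
            cv_mse={int(k): v for k, v in meta["cv_mse"].items()},
            pool_ids=pool["patient_id"].to_numpy(),
            pool_features=pool[std["columns"]].to_numpy(dtype=float),
            pool_outcomes=pool["outcome_pct"].to_numpy(),
            standardizer=params,
            medians=meta["medians"],
        )
    return models
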