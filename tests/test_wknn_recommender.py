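"""KNN prediction, K selection by cross-validation, argmax recommendation."""

import numpy as np
import pandas as pd
import pytest

from statinrec import (
    ArmMetric,
    ArmModel,
    ConfigurationError,
    CVConfig,
    StandardizationParams,
    fit_recommender,
    load_models,
    predict_arm_outcome,
    recommend,
    save_models,
    select_k,
)
from statinrec.defaults import ARMS
from statinrec.feature_matrix import FeatureSchema, FeatureSpec
from statinrec.metric_learning import LassoConfig
from statinrec.wknn_recommender import _fold_indices, _neighbor_order


def _make_model(pool_X, pool_y, weights=None, k=1, arm="none", pool_ids=None,
                feature_names=None):
    pool_X = np.asarray(pool_X, dtype=float)
    d = pool_X.shape[1]
    w = np.ones(d) if weights is None else np.asarray(weights, dtype=float)
    names = feature_names or [f"x{i}" for i in range(d)]
    metric = ArmMetric(
        arm=arm, feature_names=names, coefficients=w,
        intercept=0.0, alpha=0.1, alpha_grid=np.array([0.1]),
        n_train=len(pool_y),
    )
    ids = (
        np.array([f"P{i:03d}" for i in range(len(pool_y))])
        if pool_ids is None
        else np.asarray(pool_ids)
    )
    return ArmModel(
        metric=metric, k=k, cv_mse={k: 0.0}, pool_ids=ids,
        pool_features=pool_X, pool_outcomes=np.asarray(pool_y, dtype=float),
        standardizer=StandardizationParams(list(names), np.zeros(d), np.ones(d)),
    )


class TestPredictArmOutcome:
    def test_singleton_pool(self):
        model = _make_model([[0.0, 0.0]], [30.0], k=1)
        yhat, nbrs = predict_arm_outcome(np.array([5.0, 5.0]), model)
        assert yhat == 30.0
        assert len(nbrs) == 1

    def test_matches_full_sort_on_hand_pool(self):
        pool = np.array([[0, 0], [1, 0], [0, 2], [3, 3], [-1, -1]], float)
        y = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        model = _make_model(pool, y, k=3)
        q = np.array([0.2, 0.1])
        dists = np.linalg.norm(pool - q, axis=1)
        expect = y[np.argsort(dists, kind="stable")[:3]].mean()
        yhat, _ = predict_arm_outcome(q, model)
        assert yhat == pytest.approx(expect, abs=1e-12)

    def test_constant_outcomes_return_constant(self, rng):
        pool = rng.standard_normal((30, 4))
        model = _make_model(pool, np.full(30, 7.5), k=11)
        yhat, _ = predict_arm_outcome(rng.standard_normal(4), model)
        assert yhat == 7.5

    def test_k_exceeding_pool_raises(self):
        model = _make_model([[0.0]], [1.0], k=2)
        with pytest.raises(ConfigurationError, match="pool"):
            predict_arm_outcome(np.array([0.0]), model)

    def test_duplicate_query_with_k1_returns_its_outcome(self, rng):
        pool = rng.standard_normal((20, 3))
        y = rng.normal(0, 10, 20)
        q = pool[13].copy()
        model = _make_model(pool, y, k=1)
        yhat, nbrs = predict_arm_outcome(q, model)
        assert yhat == y[13]
        assert nbrs[0][1] == 0.0

    def test_distance_ties_break_by_ascending_patient_id(self):
        pool = np.array([[1.0], [-1.0], [1.0]])
        y = np.array([5.0, 9.0, 7.0])
        ids = np.array(["P9", "P2", "P1"])
        model = _make_model(pool, y, k=2, pool_ids=ids)
        # query 0: all three at distance 1; P1 and P2 win over P9
        yhat, nbrs = predict_arm_outcome(np.array([0.0]), model)
        assert [n[0] for n in nbrs] == ["P1", "P2"]
        assert yhat == pytest.approx((7.0 + 9.0) / 2)


def _arm_frame(n, rng, arm="high", f=None):
    x1 = rng.uniform(-2, 2, n)
    x2 = rng.standard_normal(n)
    y = f(x1) if f is not None else np.zeros(n)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "arm": arm,
            "feat_a": x1,
            "feat_b": x2,
            "outcome_pct": y,
        }
    )


_SCHEMA2 = FeatureSchema(
    [FeatureSpec("feat_a", "continuous"), FeatureSpec("feat_b", "continuous")]
)


class TestSelectK:
    def test_constant_outcome_selects_k1_by_tie_rule(self, rng):
        df = _arm_frame(60, rng)
        df["outcome_pct"] = 12.0
        k, mse = select_k(df, "high", _SCHEMA2, cv=CVConfig(fold_seed=0))
        assert k == 1
        assert all(v == pytest.approx(0.0, abs=1e-18) for v in mse.values())

    def test_smooth_signal_selects_interior_k(self, rng):
        """U-shaped CV curve: the chosen K beats both K=1 and the largest K."""
        df = _arm_frame(400, rng, f=lambda x: 10 * np.sin(x))
        df["outcome_pct"] += rng.normal(0, 2.0, 400)
        k, mse = select_k(df, "high", _SCHEMA2, cv=CVConfig(fold_seed=1))
        ks = sorted(mse)
        assert ks[0] < k <= ks[-1]
        assert mse[k] <= mse[ks[0]]
        assert mse[k] <= mse[ks[-1]]

    def test_pooled_cv_mse_matches_naive_reimplementation(self, rng):
        """Independent slow reimplementation of the fold loop agrees to 1e-9."""
        df = _arm_frame(50, rng, f=lambda x: 5 * x)
        df["outcome_pct"] += rng.normal(0, 1.0, 50)
        lcfg = LassoConfig()
        cv = CVConfig(fold_seed=7, k_grid=(1, 3, 5, 10))
        k, mse = select_k(df, "high", _SCHEMA2, lcfg, cv)

        from statinrec.feature_matrix import (
            apply_standardizer,
            assemble_features,
            fit_standardizer,
            training_medians,
        )
        from statinrec.metric_learning import fit_arm_lasso, weighted_distance

        folds = _fold_indices(len(df), cv.n_folds, cv.fold_seed)
        errors = {kk: [] for kk in mse}
        for fold in folds:
            held = df.iloc[fold]
            fit_rows = df.drop(index=df.index[fold])
            med = training_medians(fit_rows, _SCHEMA2)
            params = fit_standardizer(assemble_features(fit_rows, _SCHEMA2, med))
            Xp = apply_standardizer(
                assemble_features(fit_rows, _SCHEMA2, med), params
            ).to_numpy()
            metric = fit_arm_lasso(
                Xp, fit_rows["outcome_pct"].to_numpy(), "high", lcfg, cv.fold_seed
            )
            Xh = apply_standardizer(
                assemble_features(held, _SCHEMA2, med), params
            ).to_numpy()
            ids = fit_rows["patient_id"].to_numpy()
            ys = fit_rows["outcome_pct"].to_numpy()
            for i in range(len(held)):
                pairs = sorted(
                    (weighted_distance(Xh[i], Xp[j], metric), ids[j], ys[j])
                    for j in range(len(fit_rows))
                )
                for kk in errors:
                    yhat = np.mean([p[2] for p in pairs[:kk]])
                    errors[kk].append(
                        (yhat - held["outcome_pct"].iloc[i]) ** 2
                    )
        for kk in mse:
            assert mse[kk] == pytest.approx(np.mean(errors[kk]), abs=1e-9)

    def test_too_few_patients_raises(self, rng):
        df = _arm_frame(3, rng)
        with pytest.raises(ConfigurationError, match="fewer"):
            select_k(df, "high", _SCHEMA2, cv=CVConfig(fold_seed=0))


class TestRecommend:
    def _models_with_fixed_outcomes(self, outcomes):
        return {
            arm: _make_model([[0.0]], [val], k=1, arm=arm,
                             feature_names=["feat"])
            for arm, val in zip(ARMS, outcomes)
        }

    def _one_row(self):
        return pd.DataFrame(
            {"patient_id": ["Q1"], "feat": [0.0]}
        )

    _schema1 = FeatureSchema([FeatureSpec("feat", "continuous")])

    def test_argmax_selects_moderate_in_headline_pattern(self):
        models = self._models_with_fixed_outcomes([2.0, 10.0, 22.0, 18.0])
        recs = recommend(self._one_row(), models, self._schema1)
        assert recs["recommended_arm"].iloc[0] == "moderate"
        assert not recs["tie_flag"].iloc[0]
        assert list(recs[[f"yhat_{a}" for a in ARMS]].iloc[0]) == [
            2.0, 10.0, 22.0, 18.0,
        ]

    def test_all_equal_ties_to_none_with_flag(self):
        models = self._models_with_fixed_outcomes([5.0, 5.0, 5.0, 5.0])
        recs = recommend(self._one_row(), models, self._schema1)
        assert recs["recommended_arm"].iloc[0] == "none"
        assert recs["tie_flag"].iloc[0]

    def test_recommended_arm_attains_stored_maximum(self, policy_run):
        recs = policy_run["recommendations"]
        Y = recs[[f"yhat_{a}" for a in ARMS]].to_numpy()
        picked = recs["recommended_arm"].map(
            {a: i for i, a in enumerate(ARMS)}
        ).to_numpy()
        assert np.all(
            Y[np.arange(len(recs)), picked] >= Y.max(axis=1) - 1e-9
        )

    def test_audit_lists_k_neighbors(self, rng):
        pool = rng.standard_normal((10, 1))
        models = {
            arm: _make_model(pool, rng.normal(size=10), k=3, arm=arm,
                             feature_names=["feat"])
            for arm in ARMS
        }
        recs, audit = recommend(
            self._one_row(), models, self._schema1, audit=True
        )
        assert set(audit["Q1"]) == set(ARMS)
        assert all(len(v) == 3 for v in audit["Q1"].values())


class TestFitRecommender:
    def test_four_arms_fitted_with_full_pools(self, policy_run):
        models, train = policy_run["models"], policy_run["train"]
        assert set(models) == set(ARMS)
        for arm, m in models.items():
            n_arm = int((train["arm"] == arm).sum())
            assert len(m.pool_ids) == n_arm
            assert m.metric.n_train == n_arm
            # pool mean equals the arm's training outcome mean
            assert m.pool_outcomes.mean() == pytest.approx(
                train.loc[train["arm"] == arm, "outcome_pct"].mean(), abs=1e-9
            )
            assert m.k == min(m.cv_mse, key=lambda k: (m.cv_mse[k], k))

    def test_missing_arm_raises(self, policy_run):
        train = policy_run["train"]
        partial = train[train["arm"] != "high"]
        with pytest.raises(ConfigurationError, match="high"):
            fit_recommender(partial, policy_run["schema"])

    def test_save_load_round_trip_preserves_recommendations(
        self, policy_run, tmp_path
    ):
        models = policy_run["models"]
        save_models(models, tmp_path)
        back = load_models(tmp_path)
        test = policy_run["test"].iloc[:50]
        r1 = recommend(test, models, policy_run["schema"])
        r2 = recommend(test, back, policy_run["schema"])
        pd.testing.assert_frame_equal(r1, r2)

    def test_refit_with_same_seed_is_identical(self, rng):
        n = 160
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i:04d}" for i in range(n)],
                "arm": np.repeat(ARMS, n // 4),
                "feat_a": rng.standard_normal(n),
                "feat_b": rng.standard_normal(n),
                "outcome_pct": rng.normal(10, 5, n),
            }
        )
        cv = CVConfig(fold_seed=3, k_grid=(1, 3, 5))
        m1 = fit_recommender(df, _SCHEMA2, cv=cv)
        m2 = fit_recommender(df, _SCHEMA2, cv=cv)
        for arm in ARMS:
            assert np.array_equal(
                m1[arm].metric.coefficients, m2[arm].metric.coefficients
            )
            assert m1[arm].k == m2[arm].k
            assert m1[arm].cv_mse == m2[arm].cv_mse


class TestNeighborOrder:
    def test_lexsort_orders_by_distance_then_id(self):
        d = np.array([0.5, 0.1, 0.5, 0.0])
        ids = np.array(["D", "C", "A", "B"])
        order = _neighbor_order(d, ids)
        assert list(ids[order]) == ["B", "C", "A", "D"]

    def test_fold_partition_covers_everything_once(self):
        folds = _fold_indices(23, 5, seed=9)
        allidx = np.concatenate(folds)
        assert sorted(allidx) == list(range(23))
        assert {len(f) for f in folds} <= {4, 5}
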