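"""Dynamic logistic model: row assembly, fitting, selection, prediction, CV."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from icpdyn.model import (
    DynamicMortalityModel,
    DynamicMortalityResults,
    ModelError,
    TrainingConfig,
    _fit_core,
    _oof_auc,
    assemble_training_rows,
    rfe_select,
)
from icpdyn.evaluation import classify


def toy_feature_table():
    rows = []
    for pid, outcome in (("a", 1), ("b", 0)):
        for t in (24, 32):
            rows.append({"patient_id": pid, "t_h": t, "outcome": outcome,
                         "x1": float(t), "x2": 1.0 if pid == "a" else 0.0})
    return pd.DataFrame(rows)


def synthetic_rows(n, weights, seed, intercept=0.0):
    """Rows whose labels follow a known logistic law; one row per patient."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, len(weights))),
                     columns=[f"f{j}" for j in range(len(weights))])
    p = expit(intercept + X.to_numpy() @ np.asarray(weights))
    y = (rng.random(n) < p).astype(int)
    groups = np.arange(n).astype(str)
    return X, y, groups


class TestAssembleRows:
    def test_row_and_group_counts(self):
        X, y, groups = assemble_training_rows(toy_feature_table(), ["x1", "x2"])
        assert len(X) == 4 and len(np.unique(groups)) == 2

    def test_missing_feature_rows_dropped(self):
        table = toy_feature_table()
        table.loc[0, "x1"] = np.nan
        X, y, groups = assemble_training_rows(table, ["x1", "x2"])
        assert len(X) == 3

    def test_single_class_unfittable(self):
        table = toy_feature_table()
        table["outcome"] = 0
        with pytest.raises(ModelError):
            assemble_training_rows(table, ["x1", "x2"])

    def test_inconsistent_labels_rejected(self):
        table = toy_feature_table()
        table.loc[0, "outcome"] = 0
        with pytest.raises(ModelError):
            assemble_training_rows(table, ["x1", "x2"])


class TestFitLogistic:
    def test_null_model_limit(self):
        """Labels independent of features: weights shrink to 0, intercept to
        the log-odds of the prevalence."""
        rng = np.random.default_rng(1)
        n = 8000
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        y = (rng.random(n) < 0.3).astype(int)
        fit = _fit_core(X, y, TrainingConfig())
        assert np.all(np.abs(fit.coef) < 0.08)
        assert fit.intercept == pytest.approx(logit(y.mean()), abs=0.05)

    def test_deterministic_refit(self):
        X, y, _ = synthetic_rows(500, [1.0, -0.5], seed=2)
        a = _fit_core(X, y, TrainingConfig())
        b = _fit_core(X, y, TrainingConfig())
        assert a.intercept == b.intercept
        np.testing.assert_array_equal(a.coef, b.coef)

    def test_zero_variance_feature_dropped(self):
        X, y, _ = synthetic_rows(300, [1.0], seed=3)
        X["const"] = 5.0
        fit = _fit_core(X, y, TrainingConfig())
        assert fit.features == ["f0"]

    def test_duplication_equals_weighting(self):
        """Duplicating a patient's rows k times must match a k-weighted fit."""
        from sklearn.linear_model import LogisticRegression
        X, y, _ = synthetic_rows(300, [0.8, -0.8], seed=4)
        w = np.ones(len(X))
        w[:40] = 3.0
        dup_idx = np.concatenate([np.arange(len(X)),
                                  np.tile(np.arange(40), 2)])
        Xd, yd = X.iloc[dup_idx].reset_index(drop=True), y[dup_idx]
        config = TrainingConfig()
        fit = _fit_core(Xd, yd, config)
        # weighted fit on the original rows in the duplicated standardization;
        # match the penalty's effective strength per effective sample
        Z = (X.to_numpy() - fit.means) / fit.sds
        clf = LogisticRegression(C=config.C, solver="newton-cholesky", tol=1e-10,
                                 max_iter=500)
        clf.fit(Z, y, sample_weight=w)
        np.testing.assert_allclose(fit.coef, clf.coef_[0], atol=1e-4)
        assert fit.intercept == pytest.approx(float(clf.intercept_[0]), abs=1e-4)


class TestSelection:
    def test_rfe_grid_full_degenerates_to_full_model(self):
        X, y, groups = synthetic_rows(250, [1.0, 0.8, -0.9], seed=5)
        config = TrainingConfig(rfe_grid=(3,), n_folds=3)
        selected, report = rfe_select(X, y, groups, config)
        assert sorted(selected) == ["f0", "f1", "f2"]
        assert len(report) == 1

    def test_different_seeds_recorded(self):
        X, y, groups = synthetic_rows(300, [1.2, 0.0, 0.0], seed=6)
        sel_a, _ = rfe_select(X, y, groups, TrainingConfig(seed=1, n_folds=3))
        sel_b, _ = rfe_select(X, y, groups, TrainingConfig(seed=2, n_folds=3))
        assert "f0" in sel_a and "f0" in sel_b  # subsets may differ, signal stays

    def test_permuted_labels_cv_auc_near_half(self):
        """With features carrying no signal, out-of-fold AUC sits at chance."""
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((1000, 5)),
                         columns=[f"f{j}" for j in range(5)])
        y = rng.permutation(np.repeat([0, 1], 500))
        groups = np.arange(1000).astype(str)
        aucs = _oof_auc(X, y, groups, list(X.columns), TrainingConfig(seed=0), 0)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_too_few_patients_for_folds(self):
        X, y, _ = synthetic_rows(10, [1.0], seed=8)
        groups = np.array(["g1", "g2", "g3"] * 3 + ["g1"])
        with pytest.raises(ModelError):
            rfe_select(X, y, groups, TrainingConfig(n_folds=5))


@pytest.fixture(scope="module")
def fitted(small_features):
    model = DynamicMortalityModel(small_features, config=TrainingConfig(seed=2))
    return model, model.fit(select=False)


class TestPredictionAndResults:
    def test_probabilities_in_unit_interval(self, fitted):
        model, res = fitted
        probs = res.predict(model.feature_table).dropna()
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_standardization_round_trip(self, fitted, tmp_path):
        """A saved artifact reproduces the fit's predictions exactly."""
        model, res = fitted
        res.save(tmp_path / "model.json")
        frozen = DynamicMortalityResults.load(tmp_path / "model.json")
        a = res.predict(model.feature_table)
        b = frozen.predict(model.feature_table)
        pd.testing.assert_series_equal(a, b)

    def test_monotone_in_each_feature(self, fitted):
        """Raising a feature with a positive weight strictly raises the risk."""
        model, res = fitted
        row = model.feature_table.dropna().iloc[[0]].copy()
        base = res.predict(row).iloc[0]
        for feature in res.selected_features[:10]:
            weight = res.params[feature]
            if weight == 0:
                continue
            bumped = row.copy()
            bumped[feature] += 1.0
            delta = res.predict(bumped).iloc[0] - base
            assert math.copysign(1, delta) == math.copysign(1, weight), feature

    def test_missing_selected_feature_gives_no_prediction(self, fitted):
        model, res = fitted
        row = model.feature_table.iloc[[0]].copy()
        row[res.selected_features[0]] = np.nan
        assert res.predict(row).isna().all()

    def test_summary_mentions_features(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "intercept" in text and res.selected_features[0] in text

    def test_null_weights_give_prevalence(self):
        payload = {
            "schema_version": 1, "grammar_digest": "x",
            "selected_features": ["f0"],
            "intercept": float(logit(0.17)),
            "coef": {"f0": 0.0},
            "standardization": {"f0": {"mean": 0.0, "sd": 1.0}},
        }
        from icpdyn.model import FrozenModel
        frozen = FrozenModel(payload)
        table = pd.DataFrame({"patient_id": ["a"], "t_h": [24], "f0": [3.0]})
        assert frozen.predict(table).iloc[0] == pytest.approx(0.17)


class TestClassify:
    @pytest.mark.parametrize("p, theta, expected", [
        (0.51, 0.50, 1),
        (0.50, 0.50, 0),   # strict inequality: a tie is survival
        (0.30, 0.25, 1),
        (0.30, 0.75, 0),
    ])
    def test_strict_threshold(self, p, theta, expected):
        assert classify(p, theta) == expected

    @pytest.mark.parametrize("theta", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_domain(self, theta):
        with pytest.raises(ValueError):
            classify(0.5, theta)


class TestCrossValidation:
    def test_folds_partition_patients(self, small_features):
        model = DynamicMortalityModel(small_features,
                                      config=TrainingConfig(seed=4))
        report = model.cross_validate(select=False)
        seen = [set(c.loc[c["fold"] == k, "patient_id"])
                for k, c in enumerate([report.oof_tracks[report.oof_tracks.fold == k]
                                       for k in range(5)])]
        union = set().union(*seen)
        assert union == set(small_features["patient_id"])
        for i in range(5):
            for j in range(i + 1, 5):
                assert not seen[i] & seen[j]

    def test_fold_prevalence_stratified(self, small_features):
        model = DynamicMortalityModel(small_features,
                                      config=TrainingConfig(seed=4))
        report = model.cross_validate(select=False)
        outcomes = small_features.groupby("patient_id")["outcome"].first()
        per_fold = [
            outcomes.reindex(report.oof_tracks.loc[report.oof_tracks.fold == k,
                                                   "patient_id"].unique()).sum()
            for k in range(5)
        ]
        assert max(per_fold) - min(per_fold) <= 1
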