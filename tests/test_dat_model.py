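"""Cohort splitting, standardization, classifier training and scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from datscreen.dat_model import (
    DATModel,
    ModelConfig,
    Standardizer,
    predict_score,
    risk_band,
    score_cohort,
    split_cohort,
    standardize_fit_apply,
    train_linear,
    train_nonlinear,
    tune_hyperparameters,
)
from datscreen.epoch_features import FEATURE_COLUMNS, MODEL_FEATURES


def toy_cohort(n_per_class=20, gap=4.0, seed=0):
    """Two separable Gaussian blobs over the standard feature columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, shift in (("CP", gap), ("CN", 0.0)):
        for i in range(n_per_class):
            base = rng.normal(10.0 + shift, 1.0, len(FEATURE_COLUMNS))
            rows.append(
                {"subject_id": f"{label}{i}", "label": label}
                | {c: abs(v) for c, v in zip(FEATURE_COLUMNS, base)}
            )
    return pd.DataFrame(rows)


class TestSplit:
    def test_exact_sizes_and_stratification(self, default_cohort):
        r = split_cohort(default_cohort, 112, 60, seed=1)
        assert len(r.construction) == 112
        assert len(r.test) == 60
        assert r.construction["label"].value_counts().to_dict() == {"CP": 56, "CN": 56}
        assert r.test["label"].value_counts().to_dict() == {"CP": 30, "CN": 30}
        assert r.min_p > 0.05

    def test_deterministic(self, default_cohort):
        a = split_cohort(default_cohort, 112, 60, seed=7)
        b = split_cohort(default_cohort, 112, 60, seed=7)
        pd.testing.assert_frame_equal(a.construction, b.construction)
        pd.testing.assert_frame_equal(a.test, b.test)

    def test_disjoint(self, default_cohort):
        r = split_cohort(default_cohort, 112, 60, seed=2)
        assert not set(r.construction["subject_id"]) & set(r.test["subject_id"])

    def test_degenerate_cohort(self):
        t = toy_cohort(n_per_class=1)
        with pytest.raises(ValueError):
            split_cohort(t, 1, 1, seed=0)

    def test_infeasible_sizes(self, default_cohort):
        with pytest.raises(ValueError, match="exceeds"):
            split_cohort(default_cohort, 150, 60, seed=0)


class TestStandardizer:
    def test_hand_zscore(self):
        train = np.array([[0.0], [2.0]])
        t, _, _ = standardize_fit_apply(train)
        assert np.allclose(t.ravel(), [-1.0, 1.0])

    def test_constant_feature_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            t, _, _ = standardize_fit_apply(np.full((5, 1), 3.0))
        assert np.allclose(t, 0.0)

    def test_value_at_mean_maps_to_zero(self):
        std = Standardizer().fit(np.array([[1.0], [3.0]]))
        assert std.transform(np.array([[2.0]]))[0, 0] == 0.0


class TestLinear:
    def test_boundary_scores_fifty(self):
        model = DATModel(
            kind="linear",
            features=("a", "b"),
            center=np.zeros(2),
            scale=np.ones(2),
            weights=np.zeros(2),
            bias=0.0,
        )
        assert model.scores(np.array([[5.0, -3.0]]))[0] == pytest.approx(50.0)

    def test_zero_weights_constant_sigmoid_of_bias(self):
        model = DATModel(
            kind="linear",
            features=("a",),
            center=np.zeros(1),
            scale=np.ones(1),
            weights=np.zeros(1),
            bias=1.5,
        )
        for v in (-100.0, 0.0, 42.0):
            assert model.scores(np.array([[v]]))[0] == pytest.approx(100 * expit(1.5))

    def test_separable_toy_perfect_at_fifty(self):
        t = toy_cohort()
        model = train_linear(t)
        s = score_cohort(model, t)
        y = (t["label"] == "CP").to_numpy()
        assert ((s >= 50) == y).all()

    def test_label_flip_symmetry(self):
        t = toy_cohort(gap=2.0)
        flipped = t.assign(label=t["label"].map({"CP": "CN", "CN": "CP"}))
        s = score_cohort(train_linear(t), t)
        sf = score_cohort(train_linear(flipped), t)
        assert np.allclose(s, 100.0 - sf, atol=0.5)


class TestNonlinear:
    def test_single_base_identity(self):
        t = toy_cohort()
        cfg = ModelConfig(features=MODEL_FEATURES[:4], n_estimators=1, bootstrap=False)
        model = train_nonlinear(t, cfg, seed=0)
        Z = (t[list(cfg.features)].to_numpy(float) - model.center) / model.scale
        assert np.allclose(model.scores(t), 100.0 * model.bases[0].probability(Z))

    def test_seeded_determinism_and_roundtrip(self):
        t = toy_cohort()
        cfg = ModelConfig(n_estimators=10)
        m1 = train_nonlinear(t, cfg, seed=5)
        m2 = train_nonlinear(t, cfg, seed=5)
        assert m1.to_json() == m2.to_json()
        loaded = DATModel.from_json(m1.to_json())
        assert np.array_equal(score_cohort(m1, t), score_cohort(loaded, t))

    def test_separable_ordering(self):
        t = toy_cohort()
        model = train_nonlinear(t, ModelConfig(n_estimators=20), seed=1)
        s = score_cohort(model, t)
        cp = s[(t["label"] == "CP").to_numpy()]
        cn = s[(t["label"] == "CN").to_numpy()]
        assert cp.min() > cn.max()

    def test_oob_scores_returned(self):
        t = toy_cohort()
        model, oob = train_nonlinear(t, ModelConfig(n_estimators=30), seed=2, return_oob=True)
        assert oob.shape == (len(t),)
        assert ((oob >= 0) & (oob <= 100)).all()

    def test_scores_bounded_for_extreme_inputs(self):
        t = toy_cohort()
        model = train_nonlinear(t, ModelConfig(n_estimators=5), seed=0)
        extreme = t.copy()
        extreme[list(MODEL_FEATURES)] = 1e6
        s = score_cohort(model, extreme)
        assert ((s >= 0) & (s <= 100)).all()

    def test_ensemble_variance_shrinks_with_bagging(self, default_cohort):
        # across-seed variance of test AUC should drop from B=1 to B=25
        from datscreen.evaluation import roc_report

        r = split_cohort(default_cohort, 112, 60, seed=3)
        aucs = {1: [], 25: []}
        for b in aucs:
            for seed in range(6):
                m = train_nonlinear(
                    r.construction, ModelConfig(n_estimators=b), seed=seed
                )
                aucs[b].append(roc_report(m.scores(r.test), r.test["label"]).auc)
        assert np.var(aucs[25]) <= np.var(aucs[1]) + 1e-6


class TestTune:
    def test_single_point_grid(self, default_cohort):
        cfg = tune_hyperparameters(default_cohort, grid=[(1.0, 0.1)], seed=0)
        assert (cfg.C, cfg.gamma) == (1.0, 0.1)

    def test_duplicates_equivalent(self, default_cohort):
        a = tune_hyperparameters(default_cohort, grid=[(1.0, 0.1), (10.0, 1.0)], seed=0)
        b = tune_hyperparameters(
            default_cohort, grid=[(1.0, 0.1), (1.0, 0.1), (10.0, 1.0)], seed=0
        )
        assert (a.C, a.gamma) == (b.C, b.gamma)

    def test_matches_independent_cv_enumeration(self, default_cohort):
        # oracle: recompute every grid point's mean CV AUC independently
        from sklearn.metrics import roc_auc_score
        from sklearn.model_selection import StratifiedKFold
        from sklearn.svm import SVC

        grid = [(0.1, 0.1), (1.0, 0.1), (1.0, 1.0)]
        got = tune_hyperparameters(default_cohort, grid=grid, k=5, seed=4)
        X = default_cohort[list(MODEL_FEATURES)].to_numpy(float)
        y = (default_cohort["label"] == "CP").to_numpy().astype(int)
        folds = list(StratifiedKFold(5, shuffle=True, random_state=4).split(X, y))
        means = []
        for C, g in grid:
            aucs = []
            for tr, va in folds:
                mu, sd = X[tr].mean(0), X[tr].std(0)
                svc = SVC(C=C, gamma=g).fit((X[tr] - mu) / sd, y[tr])
                aucs.append(roc_auc_score(y[va], svc.decision_function((X[va] - mu) / sd)))
            means.append(np.mean(aucs))
        best = max(zip(means, [-c for c, _ in grid], [-g for _, g in grid], grid))[-1]
        assert (got.C, got.gamma) == best


class TestScoringInterface:
    def test_risk_bands(self):
        assert risk_band(5) == "low"
        assert risk_band(20) == "intermediate"
        assert risk_band(59.999) == "intermediate"
        assert risk_band(60) == "high"
        assert risk_band(61.1) == "high"
        with pytest.raises(ValueError):
            risk_band(101)

    def test_predict_score_names_missing_feature(self):
        t = toy_cohort()
        model = train_linear(t)
        row = {f: 1.0 for f in MODEL_FEATURES if f != "ptd"}
        with pytest.raises(KeyError, match="ptd"):
            predict_score(model, row)

    def test_predict_score_band_consistency(self):
        t = toy_cohort()
        model = train_linear(t)
        ds = predict_score(model, t.iloc[0])
        assert ds.band == risk_band(ds.value)
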