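"""SMOTE geometry, leakage-free cross-validation, tuning, consensus importance."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from sleepmr.ml import (
    ModelPerf,
    consensus_importance,
    combine_importance_profiles,
    cv_evaluate,
    default_model_panel,
    model_importances,
    smote_oversample,
    tune_hyperparameters,
)


def _blobs(n_min=20, n_maj=40, sep=10.0, d=5, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, (n_maj, d)), rng.normal(sep, 1, (n_min, d))]
    )
    y = np.array([0] * n_maj + [1] * n_min)
    return X, y


class TestSmote:
    def test_balanced_input_is_identity(self):
        X, y = _blobs(n_min=20, n_maj=20)
        Xo, yo = smote_oversample(X, y, seed=0)
        assert np.array_equal(Xo, X) and np.array_equal(yo, y)

    def test_two_minority_points_interpolate_on_segment(self):
        X = np.vstack([np.zeros((10, 2)), [[0.0, 0.0], [1.0, 1.0]]])
        y = np.array([0] * 10 + [1] * 2)
        Xo, yo = smote_oversample(X, y, seed=1)
        synth = Xo[len(X):]
        # every synthetic point lies on the segment between the two parents
        assert np.allclose(synth[:, 0], synth[:, 1], atol=1e-12)
        assert ((synth >= 0) & (synth <= 1)).all()

    def test_output_balanced_and_synthetics_convex(self):
        X, y = _blobs(n_min=10, n_maj=50, seed=2)
        Xo, yo = smote_oversample(X, y, k=5, seed=2)
        classes, counts = np.unique(yo, return_counts=True)
        assert counts[0] == counts[1] == 50
        synth = Xo[len(X):]
        Xm = X[y == 1]
        lo, hi = Xm.min(axis=0), Xm.max(axis=0)
        assert ((synth >= lo - 1e-9) & (synth <= hi + 1e-9)).all()

    def test_singleton_minority_rejected(self):
        X = np.vstack([np.zeros((5, 2)), [[1.0, 1.0]]])
        y = np.array([0] * 5 + [1])
        with pytest.raises(ValueError):
            smote_oversample(X, y)

    def test_k_truncated_with_warning(self):
        X, y = _blobs(n_min=3, n_maj=10, seed=3)
        with pytest.warns(UserWarning, match="truncated"):
            smote_oversample(X, y, k=5, seed=3)


SMALL_PANEL = {
    "logreg": lambda: LogisticRegression(max_iter=1000),
}


class TestCVEvaluate:
    def test_separable_blobs_score_perfectly(self):
        X, y = _blobs(n_min=20, n_maj=40, sep=10.0)
        perfs = cv_evaluate(X, y, SMALL_PANEL, n_folds=5, seed=42)
        p = perfs[0]
        assert p.mean("roc_auc") >= 0.99
        assert p.mean("f1_macro") == pytest.approx(1.0)
        assert p.mean("balanced_accuracy") == pytest.approx(1.0)
        assert p.mean("mcc") == pytest.approx(1.0)
        assert p.mean("brier") < 0.05

    def test_leakage_sentinel_scalers_unchanged_by_test_corruption(self):
        """Corrupting the test partition must not move the train-fitted
        standardizer: preprocessing never sees test data."""
        X, y = _blobs(n_min=15, n_maj=30, sep=3.0, seed=4)
        _, clean = cv_evaluate(
            X, y, SMALL_PANEL, n_folds=5, seed=0, collect_scalers=True
        )
        _, corrupt = cv_evaluate(
            X, y, SMALL_PANEL, n_folds=5, seed=0,
            test_transform=lambda xt: xt + 1e6, collect_scalers=True,
        )
        for (m1, s1), (m2, s2) in zip(clean, corrupt):
            assert np.array_equal(m1, m2)
            assert np.array_equal(s1, s2)

    def test_minority_class_smaller_than_folds_rejected(self):
        X, y = _blobs(n_min=4, n_maj=40)
        with pytest.raises(ValueError):
            cv_evaluate(X, y, SMALL_PANEL, n_folds=10)

    def test_deterministic_under_seed(self):
        X, y = _blobs(n_min=15, n_maj=30, sep=2.0, seed=5)
        a = cv_evaluate(X, y, SMALL_PANEL, n_folds=5, seed=9)[0]
        b = cv_evaluate(X, y, SMALL_PANEL, n_folds=5, seed=9)[0]
        assert a.fold_metrics == b.fold_metrics


class TestTuning:
    def test_budget_one_returns_single_sampled_config(self):
        X, y = _blobs(seed=6)
        params = tune_hyperparameters(
            lambda **kw: LogisticRegression(max_iter=500, **kw),
            {"C": [0.1, 1.0, 10.0]},
            X, y, budget=1, seed=0,
        )
        assert params["C"] in (0.1, 1.0, 10.0)

    def test_same_seed_same_params(self):
        X, y = _blobs(seed=7)
        kwargs = dict(budget=5, seed=3)
        f = lambda **kw: LogisticRegression(max_iter=500, **kw)
        grid = {"C": [0.01, 0.1, 1.0, 10.0]}
        assert tune_hyperparameters(f, grid, X, y, **kwargs) == tune_hyperparameters(
            f, grid, X, y, **kwargs
        )

    def test_empty_grid_returns_defaults_with_warning(self):
        X, y = _blobs(seed=8)
        with pytest.warns(UserWarning):
            assert tune_hyperparameters(
                lambda **kw: LogisticRegression(**kw), {}, X, y
            ) == {}

    def test_informative_regularization_selected_above_chance(self):
        """A usable C (1.0) should beat a crippling one (1e-6) in most seeds."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(120, 5))
        y = (X[:, 0] + 0.5 * rng.normal(size=120) > 0).astype(int)
        grid = {"C": [1e-6, 1.0]}
        wins = sum(
            tune_hyperparameters(
                lambda **kw: LogisticRegression(max_iter=500, **kw),
                grid, X, y, budget=4, seed=s,
            )["C"] == 1.0
            for s in range(10)
        )
        assert wins >= 7


class TestConsensus:
    def _perf(self, name, f1):
        return ModelPerf(name, {"f1_macro": [f1], "roc_auc": [f1],
                                "balanced_accuracy": [f1], "mcc": [f1],
                                "brier": [0.0]})

    def test_agreed_dominant_feature_tops_profile(self):
        perfs = [self._perf(f"m{i}", 0.9 - 0.01 * i) for i in range(5)]
        imps = {f"m{i}": np.array([5.0, 0.1, 0.1]) for i in range(5)}
        prof = consensus_importance(perfs, imps, top_k=5)
        assert prof.idxmax() == "f0"
        assert prof.sum() == pytest.approx(1.0)

    def test_only_top_k_models_contribute(self):
        perfs = [self._perf("good1", 0.9), self._perf("good2", 0.9),
                 self._perf("bad", 0.1)]
        imps = {
            "good1": np.array([1.0, 0.0]),
            "good2": np.array([1.0, 0.0]),
            "bad": np.array([0.0, 1.0]),
        }
        prof = consensus_importance(perfs, imps, top_k=2)
        assert prof["f0"] == pytest.approx(1.0)
        assert prof["f1"] == pytest.approx(0.0)

    def test_fewer_models_than_top_k_rejected(self):
        with pytest.raises(ValueError):
            consensus_importance([self._perf("a", 0.5)], {"a": np.ones(2)}, top_k=5)

    def test_planted_signal_outranks_noise_feature(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 80
            signal = np.concatenate([rng.normal(0, 1, n // 2),
                                     rng.normal(3, 1, n // 2)])
            X = np.column_stack([signal, rng.normal(size=n)])
            y = np.array([0] * (n // 2) + [1] * (n // 2))
            panel = default_model_panel(seed)
            perfs = cv_evaluate(X, y, panel, n_folds=5, seed=seed)
            from sklearn.preprocessing import StandardScaler

            Xs = StandardScaler().fit_transform(X)
            imps = {}
            for name, factory in panel.items():
                model = factory().fit(Xs, y)
                imps[name] = model_importances(model, Xs, y, seed)
            prof = consensus_importance(perfs, imps, top_k=5)
            wins += prof.iloc[0] > prof.iloc[1]
        assert wins == 5

    def test_overall_is_mean_of_dataset_profiles(self):
        import pandas as pd

        a = pd.Series([0.8, 0.2], index=["g1", "g2"])
        b = pd.Series([0.4, 0.6], index=["g1", "g2"])
        out = combine_importance_profiles({"d1": a, "d2": b})
        assert out.loc["g1", "overall"] == pytest.approx(0.6)
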