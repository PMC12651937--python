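"""Leakage-free cross-validated model evaluation and consensus importance.

The evaluation contract: within each stratified fold, the standardizer is
fitted exclusively on the training partition, minority oversampling (SMOTE)
is applied only to the training partition, and the test partition is
transformed with the train-fitted scaler but otherwise left in its original
imbalanced state.  All models in the panel are trained on the identical
folds.  Metrics per fold: macro F1, ROC-AUC, balanced accuracy, Matthews
correlation, Brier score.

Consensus feature importance averages L1-normalized absolute importances
(coefficients where available, impurity for tree ensembles, seeded
permutation importance otherwise) across the top models ranked by mean
macro F1; per-dataset profiles are averaged into an overall importance
score in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    balanced_accuracy_score,
    brier_score_loss,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ModelPerf",
    "smote_oversample",
    "default_model_panel",
    "cv_evaluate",
    "tune_hyperparameters",
    "consensus_importance",
    "combine_importance_profiles",
    "model_importances",
]

METRICS = ("f1_macro", "roc_auc", "balanced_accuracy", "mcc", "brier")


@dataclass
class ModelPerf:
    model_name: str
    fold_metrics: dict[str, list[float]] = field(default_factory=dict)

    def mean(self, metric: str) -> float:
        return float(np.mean(self.fold_metrics[metric]))

    def sd(self, metric: str) -> float:
        return float(np.std(self.fold_metrics[metric], ddof=1))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": list(METRICS),
                "mean": [self.mean(m) for m in METRICS],
                "sd": [self.sd(m) for m in METRICS],
            }
        )


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority oversampling.

    New minority samples are convex combinations ``x_i + u (x_nn - x_i)``
    with ``u ~ Uniform(0, 1)`` and ``x_nn`` among the k nearest minority
    neighbors (Euclidean); k is truncated to minority_size - 1 when needed.
    Already-balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_oversample expects exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if len(Xm) < 2:
        raise ValueError("minority class of size 1 has no neighbor for SMOTE")
    k_eff = min(k, len(Xm) - 1)
    if k_eff < k:
        warnings.warn(f"smote_oversample: k truncated to {k_eff}")
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]

    rng = np.random.default_rng(seed)
    base_idx = rng.integers(0, len(Xm), size=n_needed)
    pick = neigh[base_idx, rng.integers(0, k_eff, size=n_needed)]
    u = rng.uniform(size=(n_needed, 1))
    synth = Xm[base_idx] + u * (Xm[pick] - Xm[base_idx])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


def default_model_panel(seed: int = 42) -> dict:
    """Model factories spanning linear, tree-ensemble, kernel, neighbor and
    shallow neural families."""
    return {
        "logistic_regression": lambda: LogisticRegression(max_iter=2000),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=200, random_state=seed
        ),
        "gradient_boosting": lambda: GradientBoostingClassifier(
            random_state=seed
        ),
        "svm_rbf": lambda: CalibratedClassifierCV(
            SVC(random_state=seed), ensemble=False, cv=3
        ),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=2000, random_state=seed
        ),
    }


def _positive_proba(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    pos_col = int(np.argmax(model.classes_))
    return proba[:, pos_col]


def cv_evaluate(
    X,
    y,
    model_panel: dict | None = None,
    n_folds: int = 10,
    seed: int = 42,
    smote: bool = True,
    smote_k: int = 5,
    test_transform=None,
    collect_scalers: bool = False,
):
    """Stratified k-fold evaluation with per-fold scaling and oversampling.

    ``test_transform``, if given, is applied to the raw test-partition
    feature block before scaling — it exists so the no-leakage contract can
    be probed (corrupting the test partition must leave the train-fitted
    scalers untouched).  With ``collect_scalers`` the per-fold scaler means
    and scales are returned alongside the performance list.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("two classes required")
    if counts.min() < n_folds:
        raise ValueError("each class needs at least n_folds samples")
    panel = model_panel or default_model_panel(seed)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    perfs = {name: ModelPerf(name, {m: [] for m in METRICS}) for name in panel}
    scalers = []
    global_frac = counts / counts.sum()

    for train_idx, test_idx in skf.split(X, y):
        y_tr, y_te = y[train_idx], y[test_idx]
        # stratification sanity: fold class proportions within one sample
        for ci, c in enumerate(classes):
            assert abs((y_te == c).sum() - global_frac[ci] * len(y_te)) <= 1.0
        assert len(np.unique(y_te)) == 2, "fold lost a class"

        X_tr = X[train_idx]
        X_te = X[test_idx]
        if test_transform is not None:
            X_te = test_transform(X_te.copy())

        scaler = StandardScaler().fit(X_tr)
        X_tr_s = scaler.transform(X_tr)
        X_te_s = scaler.transform(X_te)
        if collect_scalers:
            scalers.append((scaler.mean_.copy(), scaler.scale_.copy()))

        if smote:
            X_fit, y_fit = smote_oversample(X_tr_s, y_tr, k=smote_k, seed=seed)
        else:
            X_fit, y_fit = X_tr_s, y_tr

        pos = classes.max()
        for name, factory in panel.items():
            model = factory()
            model.fit(X_fit, y_fit)
            y_pred = model.predict(X_te_s)
            p_pos = _positive_proba(model, X_te_s)
            fm = perfs[name].fold_metrics
            fm["f1_macro"].append(f1_score(y_te, y_pred, average="macro"))
            fm["roc_auc"].append(roc_auc_score(y_te == pos, p_pos))
            fm["balanced_accuracy"].append(
                balanced_accuracy_score(y_te, y_pred)
            )
            fm["mcc"].append(matthews_corrcoef(y_te, y_pred))
            fm["brier"].append(brier_score_loss(y_te == pos, p_pos))

    out = list(perfs.values())
    return (out, scalers) if collect_scalers else out


def tune_hyperparameters(
    model_factory,
    grid: dict,
    X,
    y,
    budget: int = 20,
    seed: int = 42,
    holdout_frac: float = 0.25,
) -> dict:
    """Seeded random search over a parameter grid, maximizing ROC-AUC on an
    inner validation split.

    ``model_factory(**params)`` must return an unfitted estimator.  An empty
    grid returns the defaults with a warning.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not grid:
        warnings.warn("tune_hyperparameters: empty grid, returning defaults")
        return {}
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=holdout_frac, stratify=y, random_state=seed
    )
    scaler = StandardScaler().fit(X_tr)
    X_tr_s, X_val_s = scaler.transform(X_tr), scaler.transform(X_val)

    rng = np.random.default_rng(seed)
    keys = sorted(grid)
    best_params, best_auc = {}, -np.inf
    pos = np.unique(y).max()
    for _ in range(budget):
        params = {k: grid[k][rng.integers(0, len(grid[k]))] for k in keys}
        model = model_factory(**params)
        model.fit(X_tr_s, y_tr)
        auc = roc_auc_score(y_val == pos, _positive_proba(model, X_val_s))
        if auc > best_auc:
            best_auc, best_params = auc, params
    return best_params


def model_importances(
    model, X_test: np.ndarray, y_test: np.ndarray, seed: int = 42
) -> np.ndarray:
    """Absolute feature importances with a hierarchical extraction rule:
    coefficients, then impurity importances, then seeded permutation
    importance as the model-agnostic fallback."""
    if hasattr(model, "coef_"):
        return np.abs(np.asarray(model.coef_)).ravel()
    if hasattr(model, "feature_importances_"):
        return np.abs(np.asarray(model.feature_importances_))
    perm = permutation_importance(
        model, X_test, y_test, n_repeats=10, random_state=seed
    )
    return np.abs(perm.importances_mean)


def consensus_importance(
    perfs: list[ModelPerf],
    per_model_importances: dict[str, np.ndarray],
    top_k: int = 5,
    feature_names: list[str] | None = None,
) -> pd.Series:
    """Average the L1-normalized importances of the top-k models by mean
    macro F1.  The returned profile sums to one."""
    if len(perfs) < top_k:
        raise ValueError(f"need at least top_k={top_k} evaluated models")
    ranked = sorted(perfs, key=lambda p: (-p.mean("f1_macro"), p.model_name))
    chosen = [p.model_name for p in ranked[:top_k]]
    profiles = []
    for name in chosen:
        imp = np.abs(np.asarray(per_model_importances[name], dtype=float))
        total = imp.sum()
        if total == 0:
            imp = np.full_like(imp, 1.0 / imp.size)
        else:
            imp = imp / total
        profiles.append(imp)
    consensus = np.mean(profiles, axis=0)
    index = feature_names or [f"f{i}" for i in range(consensus.size)]
    return pd.Series(consensus, index=index, name="importance")


def combine_importance_profiles(profiles: dict[str, pd.Series]) -> pd.DataFrame:
    """Average per-dataset consensus profiles into an overall importance score."""
    df = pd.DataFrame(profiles)
    df["overall"] = df.mean(axis=1)
    return df
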