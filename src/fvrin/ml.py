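"""Imbalance-aware classifier ensemble scoring residue mutation risk.

The learning problem: features are the per-residue structural, centrality
and conservation measures; the binary target marks residues where a
deficiency-causing missense mutation has been reported.  The dataset is
small and heavily imbalanced (about 1 positive per 20 negatives), so the
framework varies the training regimen systematically:

* 4 preprocessing combinations — always standardize; optionally reduce
  dimensionality with PCA; optionally oversample the minority class to
  parity with ADASYN;
* 5 estimator families — decision tree, random forest, gradient-boosted
  trees, SVM, and k-nearest neighbours — each tuned by grid search under
  10-fold stratified cross-validation, selecting the grid point with the
  highest mean validation ROC AUC.

Leakage discipline: standardization, PCA and ADASYN are fit on the training
folds only; validation folds are transformed but never oversampled, so fold
class ratios stay at the full-data ratio.

The five selected models vote on every residue: the vote score 0–5 counts
how many predict the deficiency class.  0 reads as "safe to substitute",
5 as most likely detrimental.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = [
    "ESTIMATORS",
    "PreprocessCombo",
    "ALL_COMBOS",
    "CVResult",
    "ModelSet",
    "adasyn",
    "get_grid",
    "grid_search_cv",
    "train_final_models",
    "ensemble_vote",
]

ESTIMATORS = ("decision_tree", "random_forest", "gradient_boosted_trees", "svm", "knn")

PCA_VARIANCE_TARGET = 0.95  # default: smallest component count explaining >= 95%


@dataclass(frozen=True)
class PreprocessCombo:
    """One of the four preprocessing regimens (standardization is always on)."""

    use_pca: bool = False
    use_oversampling: bool = False

    @property
    def name(self) -> str:
        return ("pca" if self.use_pca else "nopca") + "+" + (
            "adasyn" if self.use_oversampling else "raw"
        )


ALL_COMBOS = (
    PreprocessCombo(False, False),
    PreprocessCombo(False, True),
    PreprocessCombo(True, False),
    PreprocessCombo(True, True),
)

_LOG_RANGE = [1.0, 0.1, 0.01, 0.001, 0.0001]

#: Verbatim hyperparameter grids for the full search ("paper" preset) and
#: small grids with the identical contract for routine use ("fast" preset).
GRIDS: dict[str, dict[str, dict[str, list]]] = {
    "paper": {
        "decision_tree": {
            "criterion": ["gini", "entropy"],
            "min_samples_split": list(range(2, 51)),
            "min_samples_leaf": list(range(1, 21)),
            "ccp_alpha": _LOG_RANGE,
        },
        "random_forest": {
            "n_estimators": list(range(50, 1501, 50)),
            "max_features": list(range(2, 8)),
            "min_samples_leaf": list(range(1, 11)),
        },
        "gradient_boosted_trees": {
            "max_depth": list(range(1, 26)),
            "reg_lambda": _LOG_RANGE,
            "learning_rate": _LOG_RANGE,
        },
        "svm": {
            "kernel": ["poly", "rbf"],
            "gamma": [round(0.01 + 0.05 * i, 2) for i in range(30)],
            "degree": [2, 3, 4, 5],
            "coef0": [round(0.1 + 0.05 * i, 2) for i in range(39)],
        },
        "knn": {"n_neighbors": list(range(3, 51))},
    },
    "fast": {
        "decision_tree": {
            "criterion": ["gini"],
            "min_samples_split": [2, 10],
            "min_samples_leaf": [1, 5],
            "ccp_alpha": [0.001],
        },
        "random_forest": {
            "n_estimators": [200],
            "max_features": [3],
            "min_samples_leaf": [1, 5],
        },
        "gradient_boosted_trees": {
            "max_depth": [2, 4],
            "reg_lambda": [1.0],
            "learning_rate": [0.1, 0.3],
        },
        "svm": {"kernel": ["rbf"], "gamma": [0.05, 0.2]},
        "knn": {"n_neighbors": [5, 15, 30]},
    },
}


def get_grid(estimator: str, preset: str = "fast") -> dict[str, list]:
    if preset not in GRIDS:
        raise ValueError(f"unknown preset {preset!r}")
    if estimator not in GRIDS[preset]:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    return {k: list(v) for k, v in GRIDS[preset][estimator].items()}


def make_estimator(name: str, params: dict, seed: int = 0):
    params = dict(params)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "gradient_boosted_trees":
        # exact greedy splits (midpoint thresholds): appropriate at this data
        # size and keeps wide-margin splits centred in the margin
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0,
            tree_method="exact", **params
        )
    if name == "svm":
        return SVC(random_state=seed, **params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown estimator {name!r}")


def adasyn(
    X: np.ndarray, y: np.ndarray, seed: int = 0, k_neighbors: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive synthetic oversampling of the minority class to parity.

    Synthetic minority samples are generated by interpolation between a
    minority sample and one of its minority nearest neighbours; the number
    generated per sample is proportional to the fraction of majority
    samples among its neighbours, so hard-to-learn border regions receive
    more synthetic support.  Falls back to random duplication (with a
    warning) when the minority class has no neighbours to interpolate
    between.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("adasyn expects exactly two classes")
    minority = classes[np.argmin(counts)]
    need = int(counts.max() - counts.min())
    if need == 0:
        return X, y
    minority_idx = np.flatnonzero(y == minority)
    X_min = X[minority_idx]

    if len(X_min) < 2:
        warnings.warn("minority class has no neighbours for interpolation; duplicating at random")
        picks = rng.integers(0, len(X_min), size=need)
        X_new = X_min[picks]
    else:
        k_all = min(k_neighbors, len(X) - 1)
        nn_all = NearestNeighbors(n_neighbors=k_all + 1).fit(X)
        _, idx = nn_all.kneighbors(X_min)
        ratio = (y[idx[:, 1:]] != minority).mean(axis=1)
        if ratio.sum() == 0:
            ratio = np.ones_like(ratio)  # no border region: spread evenly
        weights = ratio / ratio.sum()
        # largest-remainder apportionment so exactly `need` samples are made
        raw = weights * need
        counts_per = np.floor(raw).astype(int)
        remainder = need - counts_per.sum()
        if remainder > 0:
            order = np.argsort(-(raw - counts_per))
            counts_per[order[:remainder]] += 1

        k_min = min(k_neighbors, len(X_min) - 1)
        nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(X_min)
        _, min_idx = nn_min.kneighbors(X_min)
        pieces = []
        for i, g in enumerate(counts_per):
            if g == 0:
                continue
            partners = min_idx[i, 1:][rng.integers(0, k_min, size=g)]
            lam = rng.random((g, 1))
            pieces.append(X_min[i] + lam * (X_min[partners] - X_min[i]))
        X_new = np.vstack(pieces) if pieces else np.empty((0, X.shape[1]))

    y_new = np.full(len(X_new), minority, dtype=y.dtype)
    return np.vstack([X, X_new]), np.concatenate([y, y_new])


class Preprocessor:
    """Standardization plus optional PCA, fit on training data only."""

    def __init__(self, use_pca: bool = False, pca_components: int | None = None):
        self.use_pca = use_pca
        self.pca_components = pca_components
        self.scaler: StandardScaler | None = None
        self.pca: PCA | None = None

    def fit(self, X: np.ndarray) -> "Preprocessor":
        self.scaler = StandardScaler().fit(X)
        Z = self.scaler.transform(X)
        if self.use_pca:
            n_components = (
                self.pca_components
                if self.pca_components is not None
                else min(PCA_VARIANCE_TARGET, 1.0)
            )
            if isinstance(n_components, float):
                n_components = min(n_components, 0.9999)
            self.pca = PCA(n_components=n_components, svd_solver="full").fit(Z)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(X)
        return self.pca.transform(Z) if self.pca is not None else Z


@dataclass
class CVResult:
    estimator: str
    combo: PreprocessCombo
    best_params: dict
    auc_mean: float
    auc_std: float
    fold_aucs: list[float] = field(default_factory=list)
    seed: int = 0


def _split_matrix(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if "label" not in matrix.columns:
        raise ValueError("feature matrix must have a 'label' column")
    feature_names = [c for c in matrix.columns if c != "label"]
    X = matrix[feature_names].to_numpy(dtype=float)
    y = matrix["label"].to_numpy(dtype=int)
    return X, y, feature_names


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def grid_search_cv(
    matrix: pd.DataFrame,
    estimator: str,
    combo: PreprocessCombo = PreprocessCombo(),
    k: int = 10,
    seed: int = 0,
    preset: str = "fast",
    grid: dict[str, list] | None = None,
    pca_components: int | None = None,
) -> CVResult:
    """Grid search one estimator under stratified k-fold CV.

    All preprocessing is fit inside training folds; the grid point with the
    highest mean validation AUC wins (ties: first in deterministic grid
    order).  Deterministic given ``seed``.
    """
    X, y, _ = _split_matrix(matrix)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    minority_count = int(counts.min())
    if minority_count < k:
        raise ValueError(
            f"minority class has {minority_count} members, fewer than k={k} folds; "
            f"use k<={minority_count}"
        )
    grid = grid if grid is not None else get_grid(estimator, preset)
    grid_points = list(ParameterGrid(grid))

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold_i, (train_idx, val_idx) in enumerate(skf.split(X, y)):
        prep = Preprocessor(combo.use_pca, pca_components).fit(X[train_idx])
        X_train = prep.transform(X[train_idx])
        y_train = y[train_idx]
        if combo.use_oversampling:
            X_train, y_train = adasyn(X_train, y_train, seed=seed + 1000 * fold_i)
        folds.append((X_train, y_train, prep.transform(X[val_idx]), y[val_idx]))

    best: tuple[float, dict, list[float]] | None = None
    for params in grid_points:
        fold_aucs = []
        for X_train, y_train, X_val, y_val in folds:
            model = make_estimator(estimator, params, seed=seed)
            model.fit(X_train, y_train)
            fold_aucs.append(roc_auc_score(y_val, _scores(model, X_val)))
        mean_auc = float(np.mean(fold_aucs))
        if best is None or mean_auc > best[0]:
            best = (mean_auc, params, fold_aucs)

    auc_mean, best_params, fold_aucs = best
    return CVResult(
        estimator=estimator,
        combo=combo,
        best_params=dict(best_params),
        auc_mean=auc_mean,
        auc_std=float(np.std(fold_aucs)),
        fold_aucs=[float(a) for a in fold_aucs],
        seed=seed,
    )


@dataclass
class ModelSet:
    """The selected classifiers, each paired with its fitted preprocessing."""

    models: dict[str, tuple[Preprocessor, object]]
    feature_names: list[str]
    seed: int

    def _design(self, matrix: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in matrix.columns]
        if missing:
            raise KeyError(f"feature matrix lacks column(s): {', '.join(missing)}")
        return matrix[self.feature_names].to_numpy(dtype=float)

    def predict_classes(self, matrix: pd.DataFrame) -> pd.DataFrame:
        X = self._design(matrix)
        out = {}
        for name, (prep, model) in self.models.items():
            out[name] = model.predict(prep.transform(X)).astype(int)
        return pd.DataFrame(out, index=matrix.index)


def train_final_models(
    matrix: pd.DataFrame, selections: list[CVResult], pca_components: int | None = None
) -> ModelSet:
    """Refit each selected estimator on the full data with its winning setup."""
    names = [s.estimator for s in selections]
    if len(set(names)) != len(names):
        raise ValueError("one CVResult per estimator expected")
    X, y, feature_names = _split_matrix(matrix)
    variances = X.var(axis=0)
    if np.any(variances == 0):
        dead = [feature_names[i] for i in np.flatnonzero(variances == 0)]
        warnings.warn(f"dropping zero-variance feature(s): {', '.join(dead)}")
        keep = variances > 0
        X = X[:, keep]
        feature_names = [f for f, ok in zip(feature_names, keep) if ok]

    models: dict[str, tuple[Preprocessor, object]] = {}
    for sel in selections:
        prep = Preprocessor(sel.combo.use_pca, pca_components).fit(X)
        X_fit, y_fit = prep.transform(X), y
        if sel.combo.use_oversampling:
            X_fit, y_fit = adasyn(X_fit, y_fit, seed=sel.seed)
        model = make_estimator(sel.estimator, sel.best_params, seed=sel.seed)
        model.fit(X_fit, y_fit)
        models[sel.estimator] = (prep, model)
    return ModelSet(models=models, feature_names=feature_names, seed=selections[0].seed)


def ensemble_vote(models: ModelSet, matrix: pd.DataFrame) -> pd.Series:
    """Vote score per residue: how many models predict the deficiency class.

    Each model casts a vote at its decision boundary (0.5 probability for
    probabilistic models).  0 = predicted safe to substitute by all models;
    the maximum = predicted detrimental by all.
    """
    classes = models.predict_classes(matrix)
    return classes.sum(axis=1).rename("vote")
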