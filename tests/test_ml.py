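"""Classifier-ensemble framework: leakage discipline, grids, votes, determinism."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import ParameterGrid, StratifiedKFold

import fvrin.ml as ml
from fvrin.ml import (
    ALL_COMBOS,
    ESTIMATORS,
    PreprocessCombo,
    Preprocessor,
    adasyn,
    ensemble_vote,
    get_grid,
    grid_search_cv,
    make_estimator,
    train_final_models,
)
from fvrin.synthetic import SyntheticSpec, generate_feature_table

TINY_GRIDS = {
    "decision_tree": {"criterion": ["gini"], "min_samples_leaf": [3]},
    "random_forest": {"n_estimators": [60], "max_features": [3]},
    "gradient_boosted_trees": {"max_depth": [2], "learning_rate": [0.3]},
    "svm": {"kernel": ["rbf"], "gamma": [0.1]},
    "knn": {"n_neighbors": [7]},
}


def separable_table(n=240, n_pos=48, seed=0):
    spec = SyntheticSpec(
        n_residues=n, n_deficient=n_pos, effect_sizes={"degree": 10.0}, seed=seed
    )
    return generate_feature_table(spec)


def noise_table(n=240, n_pos=24, seed=0):
    return generate_feature_table(
        SyntheticSpec(n_residues=n, n_deficient=n_pos, effect_sizes={}, seed=seed)
    )


@pytest.mark.parametrize("estimator", ESTIMATORS)
def test_separable_classes_reach_perfect_auc(estimator):
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "signal": np.concatenate([rng.normal(0, 1, 192), rng.normal(10, 1, 48)]),
            "label": [0] * 192 + [1] * 48,
        }
    )
    grid = dict(TINY_GRIDS[estimator])
    if estimator == "random_forest":
        grid["max_features"] = [1]
    result = grid_search_cv(table, estimator, PreprocessCombo(), k=5, seed=0, grid=grid)
    assert result.auc_mean == pytest.approx(1.0)


def test_knn_full_grid_has_48_points():
    grid = get_grid("knn", preset="paper")
    assert grid["n_neighbors"] == list(range(3, 51))
    assert len(list(ParameterGrid(grid))) == 48


def test_full_grids_match_declared_ranges():
    svm = get_grid("svm", preset="paper")
    assert svm["gamma"][0] == 0.01 and svm["gamma"][-1] == pytest.approx(1.46)
    assert len(svm["gamma"]) == 30
    tree = get_grid("decision_tree", preset="paper")
    assert tree["ccp_alpha"] == [1.0, 0.1, 0.01, 0.001, 0.0001]
    forest = get_grid("random_forest", preset="paper")
    assert forest["n_estimators"][0] == 50 and forest["n_estimators"][-1] == 1500


def test_minority_smaller_than_k_is_an_error():
    table = separable_table(n=100, n_pos=4)
    with pytest.raises(ValueError, match="k<=4"):
        grid_search_cv(table, "knn", k=10, grid=TINY_GRIDS["knn"])


def test_oversampling_touches_training_folds_only(monkeypatch):
    """ADASYN input sizes must equal training-fold sizes, and validation
    folds keep the full-data class ratio (±1 instance)."""
    table = noise_table(n=200, n_pos=40, seed=1)
    y = table["label"].to_numpy()
    k = 5
    calls = []
    original = ml.adasyn

    def recording_adasyn(X, yy, **kwargs):
        calls.append(len(yy))
        return original(X, yy, **kwargs)

    monkeypatch.setattr(ml, "adasyn", recording_adasyn)
    grid_search_cv(
        table, "knn", PreprocessCombo(use_oversampling=True), k=k, seed=3,
        grid=TINY_GRIDS["knn"],
    )
    fold_sizes = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=3)
    full_ratio = y.mean()
    for train_idx, val_idx in skf.split(np.zeros_like(y), y):
        fold_sizes.append(len(train_idx))
        n_val_pos = y[val_idx].sum()
        assert abs(n_val_pos - full_ratio * len(val_idx)) <= 1.0
    assert sorted(calls) == sorted(fold_sizes)


def test_pure_noise_auc_is_near_chance():
    aucs = []
    for seed in range(6):
        table = noise_table(seed=seed)
        result = grid_search_cv(
            table, "knn", PreprocessCombo(), k=5, seed=seed, grid=TINY_GRIDS["knn"]
        )
        aucs.append(result.auc_mean)
    assert 0.40 <= float(np.mean(aucs)) <= 0.60


def test_adasyn_balances_classes_exactly():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, (120, 4)), rng.normal(2, 1, (15, 4))])
    y = np.array([0] * 120 + [1] * 15)
    Xr, yr = adasyn(X, y, seed=1)
    counts = np.bincount(yr)
    assert counts[0] == counts[1] == 120
    # originals are retained untouched
    np.testing.assert_array_equal(Xr[: len(X)], X)


def test_adasyn_without_minority_neighbours_falls_back_to_duplication():
    X = np.vstack([np.zeros((10, 2)), np.ones((1, 2))])
    y = np.array([0] * 10 + [1])
    with pytest.warns(UserWarning, match="duplicat"):
        Xr, yr = adasyn(X, y, seed=0)
    assert np.bincount(yr)[1] == 10


def test_vote_counts_models_predicting_deficiency():
    table = separable_table(n=200, n_pos=40, seed=2)
    selections = [
        grid_search_cv(table, est, PreprocessCombo(), k=5, seed=2, grid=TINY_GRIDS[est])
        for est in ESTIMATORS
    ]
    models = train_final_models(table, selections)
    votes = ensemble_vote(models, table)
    classes = models.predict_classes(table)
    # the vote is the manual count over the five per-model predictions
    np.testing.assert_array_equal(votes.to_numpy(), classes.sum(axis=1).to_numpy())
    assert votes.between(0, 5).all()
    # perfectly separated: positives get 5 votes, negatives 0
    assert votes[table["label"] == 1].min() >= 4
    assert votes[table["label"] == 0].median() == 0


def test_refit_with_same_seed_is_deterministic():
    table = separable_table(n=200, n_pos=40, seed=3)
    selections = [
        grid_search_cv(table, est, PreprocessCombo(), k=5, seed=7, grid=TINY_GRIDS[est])
        for est in ("decision_tree", "random_forest")
    ]
    votes_a = ensemble_vote(train_final_models(table, selections), table)
    votes_b = ensemble_vote(train_final_models(table, selections), table)
    np.testing.assert_array_equal(votes_a.to_numpy(), votes_b.to_numpy())


def test_final_models_match_refit_by_hand_oracle():
    table = separable_table(n=160, n_pos=32, seed=4)
    sel = grid_search_cv(
        table, "decision_tree", PreprocessCombo(use_pca=True), k=5, seed=5,
        grid=TINY_GRIDS["decision_tree"],
    )
    models = train_final_models(table, [sel])
    X = table[[c for c in table.columns if c != "label"]].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    prep = Preprocessor(use_pca=True).fit(X)
    hand = make_estimator("decision_tree", sel.best_params, seed=5).fit(prep.transform(X), y)
    np.testing.assert_array_equal(
        models.predict_classes(table)["decision_tree"].to_numpy(),
        hand.predict(prep.transform(X)),
    )


def test_zero_variance_feature_is_dropped_with_warning():
    table = separable_table(n=160, n_pos=32, seed=5)
    table["pagerank"] = 1.0
    sel = grid_search_cv(table, "knn", PreprocessCombo(), k=5, seed=0, grid=TINY_GRIDS["knn"])
    with pytest.warns(UserWarning, match="pagerank"):
        models = train_final_models(table, [sel])
    assert "pagerank" not in models.feature_names


def test_missing_feature_column_is_named():
    table = separable_table(n=160, n_pos=32, seed=6)
    sel = grid_search_cv(table, "knn", PreprocessCombo(), k=5, seed=0, grid=TINY_GRIDS["knn"])
    models = train_final_models(table, [sel])
    with pytest.raises(KeyError, match="closeness"):
        ensemble_vote(models, table.drop(columns=["closeness"]))


def test_combo_names_cover_the_four_regimens():
    assert {c.name for c in ALL_COMBOS} == {
        "nopca+raw", "nopca+adasyn", "pca+raw", "pca+adasyn"
    }
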