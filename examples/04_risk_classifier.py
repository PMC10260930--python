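"""Train the classifier ensemble and score every residue's mutation risk.

Runs a reduced sweep (two estimator families, all four preprocessing
regimens) on the study-calibrated synthetic table, refits the winners and
prints the vote-score distribution.
"""

from fvrin.ml import ALL_COMBOS, ensemble_vote, grid_search_cv, train_final_models
from fvrin.synthetic import generate_feature_table, study_calibrated_spec

table = generate_feature_table(study_calibrated_spec(seed=0))

results = [
    grid_search_cv(table, estimator, combo, k=10, seed=0, preset="fast")
    for estimator in ("svm", "gradient_boosted_trees")
    for combo in ALL_COMBOS
]
for r in sorted(results, key=lambda r: -r.auc_mean):
    print(f"{r.estimator:<14} {r.combo.name:<13} AUC {r.auc_mean:.3f} +/- {r.auc_std:.3f}")

selections = [
    max((r for r in results if r.estimator == est), key=lambda r: r.auc_mean)
    for est in ("svm", "gradient_boosted_trees")
]
models = train_final_models(table, selections)
votes = ensemble_vote(models, table)
print("\nvote distribution (0 = all models say safe to substitute):")
print(votes.value_counts().sort_index().to_string())
# An AUC around 0.65-0.70 under these conditions is a fair signal: the
# planted effects are moderate and the deficiency class is tiny, so perfect
# separation is impossible by construction.
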