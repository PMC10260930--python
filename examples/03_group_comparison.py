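"""Compare deficiency-associated residues to the rest, feature by feature.

Generates a feature table at the study's 63/1254 imbalance with planted
effects (deficiency residues more central, less exposed, more conserved)
and runs the subsample-bootstrap median test on every feature.
"""

from fvrin.features import FEATURE_NAMES
from fvrin.stats import bootstrap_median_test
from fvrin.synthetic import generate_feature_table, study_calibrated_spec

table = generate_feature_table(study_calibrated_spec(seed=0))
deficient = table["label"] == 1

print(f"{'feature':<18} {'median(def)':>12} {'median(rest)':>13} {'p':>8}")
for feature in FEATURE_NAMES:
    result = bootstrap_median_test(
        table.loc[~deficient, feature],
        table.loc[deficient, feature],
        n_iter=10_000,
        seed=0,
        feature=feature,
    )
    print(
        f"{feature:<18} {result.median_small:>12.3f} "
        f"{result.median_large_full:>13.3f} {result.p_value:>8.4f}"
    )
# p near 0: the deficiency group sits HIGH on that feature (e.g. degree);
# p near 1: it sits LOW (e.g. surface areas, conservation score where low
# means conserved); p near 0.5: no separation (phi/psi carry no effect).
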