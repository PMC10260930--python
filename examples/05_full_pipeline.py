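"""Run the whole pipeline on a generated fixture directory.

Writes a toy structure + conservation + label CSVs, then executes every
stage (network, centralities, features, criticality, group comparison,
training, vote scoring) into a run directory with a manifest.
"""

import json
import tempfile
from pathlib import Path

from fvrin.pipeline import RunConfig, run_pipeline
from fvrin.synthetic import write_fixture_set

workdir = Path(tempfile.mkdtemp(prefix="fvrin_example_"))
fixtures = write_fixture_set(workdir / "fixtures", n_res=60, n_labeled=14, seed=0)

config = RunConfig(
    structure=str(fixtures["structure"]),
    conservation=str(fixtures["conservation"]),
    labels=str(fixtures["labels"]),
    outdir=str(workdir / "run"),
    cv_folds=5,
    bootstrap_iterations=2000,
    estimators=["decision_tree", "knn", "svm"],
    seed=0,
)
outdir = run_pipeline(config)

manifest = json.loads((outdir / "manifest.json").read_text())
print("stages executed:", ", ".join(manifest["stages"]))
print("outputs:")
for path in sorted(outdir.iterdir()):
    print(f"  {path.name}")
# The same run is reproducible byte-for-byte given the same config seed;
# the manifest records the per-stage seeds and a config hash.
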