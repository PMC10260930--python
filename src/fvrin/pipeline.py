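"""End-to-end pipeline: structure → network → features → statistics → votes.

Stages run in dependency order and each writes its CSV into the run
directory; a ``manifest.json`` records stage names, seeds and parameter
hashes so a run is reproducible and auditable.  All randomness derives from
the single config seed, fanned out per stage as ``seed + STAGE_OFFSET``
(offsets are fixed constants), so partial reruns of a stage are
reproducible in isolation.

Residue identity in every serialized table is (chain, author seqnum,
icode) — 1-based author numbering, never a 0-based index.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import centrality, contacts, criticality, features, ml, stats
from .structure import ResidueKey, parse_structure

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config", "STAGES"]

STAGES = (
    "build-rin",
    "centrality",
    "features",
    "criticality",
    "compare-groups",
    "train",
    "score",
)

# per-stage seed offsets (documented derivation: config.seed + offset)
SEED_OFFSETS = {"compare-groups": 101, "train": 202, "score": 303}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    structure: str = ""
    conservation: str = ""
    labels: str = ""
    outdir: str = "fvrin_run"
    chains: list[str] | None = None
    probe_radius: float = 0.25
    min_seq_separation: int = 1
    n_bins: int = 4
    bootstrap_iterations: int = 10_000
    ml_preset: str = "fast"
    combos: str = "all"  # "all" or one of the 4 combo names
    estimators: list[str] = field(default_factory=lambda: list(ml.ESTIMATORS))
    cv_folds: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in ("structure", "conservation", "labels"):
            path = getattr(self, name)
            if not path or not Path(path).is_file():
                raise PipelineError(f"config: {name} file not found: {path!r}")
        if self.ml_preset not in ("paper", "fast"):
            raise PipelineError(f"config: unknown ml_preset {self.ml_preset!r}")
        combo_names = [c.name for c in ml.ALL_COMBOS]
        if self.combos != "all" and self.combos not in combo_names:
            raise PipelineError(f"config: combos must be 'all' or one of {combo_names}")
        unknown = set(self.estimators) - set(ml.ESTIMATORS)
        if unknown:
            raise PipelineError(f"config: unknown estimator(s) {sorted(unknown)}")
        if self.n_bins < 2 or self.cv_folds < 2 or self.bootstrap_iterations < 1:
            raise PipelineError("config: n_bins, cv_folds and bootstrap_iterations must be >= 2/2/1")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
    return RunConfig(**raw)


def _read_residue_csv(path: str, value_column: str) -> pd.Series:
    table = pd.read_csv(path, dtype={"chain": str, "icode": str}, keep_default_na=False)
    for needed in ("chain", "seqnum", value_column):
        if needed not in table.columns:
            raise PipelineError(f"{path}: missing column {value_column!r}")
    icode = table["icode"] if "icode" in table.columns else ""
    keys = [
        ResidueKey(str(c), int(s), str(i).strip())
        for c, s, i in zip(table["chain"], table["seqnum"], icode)
    ]
    return pd.Series(
        table[value_column].to_numpy(),
        index=pd.Index(keys, name="residue", tupleize_cols=False),
    )


def _residue_frame(index: pd.Index) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chain": [k.chain for k in index],
            "seqnum": [k.seqnum for k in index],
            "icode": [k.icode for k in index],
        }
    )


def _write(table: pd.DataFrame, path: Path) -> None:
    out = pd.concat(
        [_residue_frame(table.index), table.reset_index(drop=True)], axis=1
    )
    out.to_csv(path, index=False)


def _param_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the run directory.

    Any stage failure raises :class:`PipelineError` naming the stage.
    Reruns with the same config and seed produce byte-identical CSVs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "stages": [],
        "seed": config.seed,
        "config_hash": _param_hash(config),
        "config": dataclasses.asdict(config),
    }

    def stage(name: str):
        manifest["stages"].append(name)

    try:
        stage("build-rin")
        structure = parse_structure(Path(config.structure).read_text())
        if config.chains:
            keep = {k: r for k, r in structure.residues.items() if k.chain in config.chains}
            structure.residues = keep
            if not keep:
                raise PipelineError("build-rin: chain filter removed every residue")
        rule = contacts.ContactRule(
            probe_radius=config.probe_radius, min_seq_separation=config.min_seq_separation
        )
        graph = contacts.build_rin(structure, rule)
        with open(outdir / "edges.csv", "w") as fh:
            contacts.write_edge_table(graph, fh)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"build-rin: {exc}") from exc

    try:
        stage("centrality")
        cent = centrality.compute_centralities(graph)
        _write(cent, outdir / "centrality.csv")
        spearman = centrality.spearman_matrix(cent)
        spearman.to_csv(outdir / "centrality_spearman.csv")
    except Exception as exc:
        raise PipelineError(f"centrality: {exc}") from exc

    try:
        stage("features")
        structural = features.structural_feature_table(structure, sesa_fallback=True)
        conservation = _read_residue_csv(config.conservation, "score")
        labels = _read_residue_csv(config.labels, "label")
        matrix, drop_log = features.assemble_feature_matrix(
            cent, structural, conservation, labels
        )
        _write(matrix, outdir / "feature_matrix.csv")
        drop_log.to_csv(outdir / "dropped_rows.csv")
    except Exception as exc:
        raise PipelineError(f"features: {exc}") from exc

    try:
        stage("criticality")
        report, grid = criticality.criticality_table(cent, config.n_bins)
        _write(report, outdir / "criticality.csv")
        manifest["bin_grid"] = {
            "degree_edges": list(grid.degree_edges),
            "logbet_edges": list(grid.logbet_edges),
        }
    except Exception as exc:
        raise PipelineError(f"criticality: {exc}") from exc

    try:
        stage("compare-groups")
        seed = config.seed + SEED_OFFSETS["compare-groups"]
        rows = []
        small_mask = matrix["label"] == 1
        for feature_name in features.FEATURE_NAMES:
            small = matrix.loc[small_mask, feature_name]
            large = matrix.loc[~small_mask, feature_name]
            if len(small) == 0 or len(large) < len(small):
                continue
            result = stats.bootstrap_median_test(
                large, small, n_iter=config.bootstrap_iterations, seed=seed,
                feature=feature_name,
            )
            rows.append(dataclasses.asdict(result))
        pd.DataFrame(rows).to_csv(outdir / "group_comparison.csv", index=False)
    except Exception as exc:
        raise PipelineError(f"compare-groups: {exc}") from exc

    try:
        stage("train")
        seed = config.seed + SEED_OFFSETS["train"]
        combos = (
            list(ml.ALL_COMBOS)
            if config.combos == "all"
            else [c for c in ml.ALL_COMBOS if c.name == config.combos]
        )
        leaderboard: list[ml.CVResult] = []
        for estimator in config.estimators:
            for combo in combos:
                leaderboard.append(
                    ml.grid_search_cv(
                        matrix, estimator, combo, k=config.cv_folds,
                        seed=seed, preset=config.ml_preset,
                    )
                )
        board = pd.DataFrame(
            {
                "estimator": [r.estimator for r in leaderboard],
                "combo": [r.combo.name for r in leaderboard],
                "auc_mean": [r.auc_mean for r in leaderboard],
                "auc_std": [r.auc_std for r in leaderboard],
                "best_params": [json.dumps(r.best_params, sort_keys=True) for r in leaderboard],
                "seed": [r.seed for r in leaderboard],
            }
        )
        board.to_csv(outdir / "cv_leaderboard.csv", index=False)
        selections = []
        for estimator in config.estimators:
            candidates = [r for r in leaderboard if r.estimator == estimator]
            selections.append(max(candidates, key=lambda r: r.auc_mean))
        model_set = ml.train_final_models(matrix, selections)
        manifest["selected_models"] = {
            s.estimator: {"combo": s.combo.name, "auc_mean": s.auc_mean,
                          "best_params": s.best_params}
            for s in selections
        }
    except Exception as exc:
        raise PipelineError(f"train: {exc}") from exc

    try:
        stage("score")
        votes = ml.ensemble_vote(model_set, matrix)
        vote_table = votes.to_frame()
        vote_table = vote_table.sort_values("vote", ascending=False, kind="stable")
        _write(vote_table, outdir / "vote_scores.csv")
    except Exception as exc:
        raise PipelineError(f"score: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
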