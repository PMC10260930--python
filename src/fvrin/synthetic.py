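"""Synthetic inputs for every stage of the pipeline.

Three generators keep the whole analysis testable without any downloads:

* :func:`generate_toy_structure` — a poly-alanine backbone built from ideal
  bond lengths/angles and caller-chosen (phi, psi) torsions, so geometric
  code (parsing round-trips, dihedral recovery, contact detection) can be
  checked against known ground truth;
* :func:`generate_feature_table` — a complete feature matrix with the
  deficiency label and *planted* feature–label effects at a chosen class
  imbalance, so the statistics and the classifier ensemble can be exercised
  under known effect sizes;
* :func:`generate_random_graph` — seeded random graphs as substrate for the
  centrality and criticality oracles.

The "study-calibrated" preset mirrors the real dataset's conditions: 1317
residues with 63 deficiency-labelled (4.78% vs 95.22%), moderate planted
effects in the directions seen on the real protein — deficiency residues
more central, less surface-exposed, more conserved — and mild inter-feature
correlation through a shared latent factor.

Centrality columns in generated feature tables are *drawn*, not computed
from a generated graph: the table generator exists to test the downstream
statistics and learning machinery in isolation.  End-to-end runs that
compute centralities from a generated structure go through the pipeline
instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .structure import Atom, Residue, ResidueKey, Structure, write_structure

__all__ = [
    "SyntheticSpec",
    "study_calibrated_spec",
    "generate_toy_structure",
    "generate_feature_table",
    "generate_random_graph",
    "write_fixture_set",
]

# ideal backbone geometry: bond lengths (Å) and angles (degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_B_C_O, _B_CA_CB = 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_C_CA_CB = 120.5, 110.1
_OMEGA = 180.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for a generated feature table.

    ``effect_sizes`` are shifts of the deficient group in pooled-SD units
    (noise is unit-SD Normal, so the shift *is* the effect size); positive
    means the deficient group is higher.  ``correlation`` injects a shared
    latent factor across features.
    """

    n_residues: int = 1317
    n_deficient: int = 63
    effect_sizes: dict[str, float] = field(default_factory=dict)
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_deficient > self.n_residues:
            raise ValueError("n_deficient cannot exceed n_residues")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [0, 1)")
        if any(not math.isfinite(v) for v in self.effect_sizes.values()):
            raise ValueError("effect sizes must be finite")
        if self.n_deficient == 0 and any(v != 0 for v in self.effect_sizes.values()):
            raise ValueError("nonzero effects require a deficient group to shift")
        unknown = set(self.effect_sizes) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature(s) in effect_sizes: {sorted(unknown)}")


def study_calibrated_spec(seed: int = 0) -> SyntheticSpec:
    """The study-conditions preset: 63/1254 imbalance, moderate planted effects.

    Effect directions follow the pattern observed on the real protein:
    deficiency residues sit at the core (lower surface areas, higher
    hydrophobicity), are more central by every measure except Burt's
    constraint (low constraint = broker), and are more conserved (the
    conservation score convention is low = conserved, hence negative).
    """
    return SyntheticSpec(
        n_residues=1317,
        n_deficient=63,
        effect_sizes={
            "kd_hydrophobicity": 0.2,
            "sasa": -0.4,
            "sesa": -0.4,
            "relative_sesa": -0.4,
            "degree": 0.4,
            "betweenness": 0.3,
            "closeness": 0.3,
            "kcore": 0.3,
            "burts_constraint": -0.2,
            "authority": 0.25,
            "pagerank": 0.25,
            "conservation": -0.4,
        },
        correlation=0.5,
        seed=seed,
    )


def _normalize_angle(angle: float) -> float:
    wrapped = ((angle + 180.0) % 360.0) - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of the next atom.

    Returns the point at distance ``bond`` from ``c``, with angle b-c-new
    equal to ``angle_deg`` and dihedral a-b-c-new equal to ``torsion_deg``.
    """
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d


def generate_toy_structure(
    n_res: int,
    torsions: tuple[float, float] = (-57.0, -47.0),
    seed: int = 0,
    chain: str = "A",
    with_cb: bool = True,
) -> Structure:
    """Ideal-geometry poly-alanine backbone with the requested (phi, psi).

    Deterministic; the ``seed`` parameter is part of the generator API for
    symmetry with the other generators but introduces no randomness here.
    Torsions outside (-180, 180] are normalized with a warning.
    """
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    phi, psi = torsions
    if not (-180.0 < phi <= 180.0) or not (-180.0 < psi <= 180.0):
        warnings.warn("torsions outside (-180, 180] were normalized")
        phi, psi = _normalize_angle(phi), _normalize_angle(psi)

    # seed the first three backbone atoms of residue 1 explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    angle = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(angle), math.sin(angle), 0.0])

    backbone: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [(n0, ca0, c0)]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_i = _place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = _place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        backbone.append((n_i, ca_i, c_i))

    structure = Structure()
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        atoms = [
            Atom("N", "N", n_i),
            Atom("CA", "C", ca_i),
            Atom("C", "C", c_i),
        ]
        # carbonyl oxygen: anti-periplanar to the next amide nitrogen
        if i < n_res - 1:
            next_n = backbone[i + 1][0]
            o_i = _place_atom(next_n, ca_i, c_i, _B_C_O, _A_CA_C_O, 180.0)
        else:
            o_i = _place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, psi + 180.0)
        atoms.append(Atom("O", "O", o_i))
        if with_cb:
            cb = _place_atom(n_i, c_i, ca_i, _B_CA_CB, _A_C_CA_CB, -122.0)
            atoms.append(Atom("CB", "C", cb))
        structure.residues[ResidueKey(chain, i + 1, "")] = Residue("ALA", atoms)
    return structure


def generate_feature_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Complete 14-feature matrix with a planted-effect deficiency label.

    Per feature the noise is unit-SD Normal; a shared latent factor injects
    ``spec.correlation`` pairwise correlation; deficient rows are shifted by
    ``spec.effect_sizes``.  Bit-reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_residues, len(FEATURE_NAMES)
    rho = spec.correlation
    latent = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, k))
    # the latent factor plays the role of burial depth: each feature loads
    # on it with the sign of its association (surface areas negatively,
    # centralities positively), so correlations between features carry the
    # same sign structure as the planted effects
    loading = np.array(
        [-1.0 if spec.effect_sizes.get(f, 0.0) < 0 else 1.0 for f in FEATURE_NAMES]
    )
    values = math.sqrt(rho) * latent * loading + math.sqrt(1.0 - rho) * noise

    labels = np.zeros(n, dtype=int)
    deficient = rng.choice(n, size=spec.n_deficient, replace=False)
    labels[deficient] = 1
    for j, feature in enumerate(FEATURE_NAMES):
        shift = spec.effect_sizes.get(feature, 0.0)
        if shift:
            values[deficient, j] += shift

    index = pd.Index(
        [ResidueKey("A", i + 1, "") for i in range(n)], name="residue", tupleize_cols=False
    )
    table = pd.DataFrame(values, columns=list(FEATURE_NAMES), index=index)
    table["label"] = labels
    return table


def generate_random_graph(
    n: int, model: str = "erdos_renyi", params: dict | None = None, seed: int = 0
) -> nx.Graph:
    """Seeded simple random graph (Erdős–Rényi G(n, p) or Barabási–Albert)."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    params = params or {}
    if model == "erdos_renyi":
        p = params.get("p", 0.1)
        if not 0.0 <= p <= 1.0:
            raise ValueError("edge probability p must be in [0, 1]")
        return nx.gnp_random_graph(n, p, seed=seed)
    if model == "barabasi_albert":
        m = params.get("m", 2)
        if not 1 <= m < n:
            raise ValueError("attachment count m must satisfy 1 <= m < n")
        return nx.barabasi_albert_graph(n, m, seed=seed)
    raise ValueError(f"unknown graph model {model!r}")


def write_fixture_set(
    outdir: str | Path,
    n_res: int = 60,
    n_labeled: int = 12,
    seed: int = 0,
    torsions: tuple[float, float] = (-57.0, -47.0),
) -> dict[str, Path]:
    """Write a PDB + conservation CSV + label CSV fixture directory.

    The conservation column is random (low = conserved) and the labelled
    positions are a random subset — enough to drive the full pipeline.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    structure = generate_toy_structure(n_res, torsions=torsions, seed=seed)

    pdb_path = outdir / "structure.pdb"
    pdb_path.write_text(write_structure(structure))

    keys = structure.keys()
    conservation = pd.DataFrame(
        {
            "chain": [k.chain for k in keys],
            "seqnum": [k.seqnum for k in keys],
            "icode": [k.icode for k in keys],
            "score": np.round(rng.uniform(1.0, 9.0, size=len(keys)), 3),
        }
    )
    cons_path = outdir / "conservation.csv"
    conservation.to_csv(cons_path, index=False)

    labeled = rng.choice(len(keys), size=min(n_labeled, len(keys)), replace=False)
    labels = pd.DataFrame(
        {
            "chain": [keys[i].chain for i in sorted(labeled)],
            "seqnum": [keys[i].seqnum for i in sorted(labeled)],
            "icode": [keys[i].icode for i in sorted(labeled)],
            "label": 1,
        }
    )
    labels_path = outdir / "labels.csv"
    labels.to_csv(labels_path, index=False)
    return {"structure": pdb_path, "conservation": cons_path, "labels": labels_path}
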