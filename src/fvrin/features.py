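"""Per-residue structural features and assembly of the 14-feature matrix.

The feature block combines three sources:

* six structural features computed (or imported) from the structure —
  Kyte–Doolittle hydrophobicity, solvent-accessible surface area (SASA,
  Shrake–Rupley), solvent-excluded surface area (SESA, imported by default),
  relative SESA against a Gly-X-Gly tripeptide reference state, and the
  backbone dihedral angles phi and psi;
* seven network centralities (see :mod:`fvrin.centrality`);
* one evolutionary conservation score, imported as a column (convention:
  low values indicate high conservation).

Rows with any missing feature, or with zero betweenness, are dropped during
assembly and logged with a reason, leaving a complete matrix with a binary
deficiency label per residue.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .contacts import DEFAULT_VDW
from .structure import ResidueKey, Structure

__all__ = [
    "FEATURE_NAMES",
    "KD_HYDROPHOBICITY",
    "kd_hydrophobicity",
    "backbone_dihedrals",
    "sasa",
    "relative_accessibility",
    "load_gxg_reference",
    "structural_feature_table",
    "assemble_feature_matrix",
]

#: Fixed, ordered registry of the 14 model features.
FEATURE_NAMES = (
    "kd_hydrophobicity",
    "sasa",
    "sesa",
    "relative_sesa",
    "phi",
    "psi",
    "degree",
    "betweenness",
    "closeness",
    "kcore",
    "burts_constraint",
    "authority",
    "pagerank",
    "conservation",
)

#: Kyte–Doolittle hydropathy scale (positive = hydrophobic).
KD_HYDROPHOBICITY = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

CHAIN_BREAK_DISTANCE = 2.5  # Å between C(i) and N(i+1)


def kd_hydrophobicity(resname: str) -> float:
    """Kyte–Doolittle hydropathy of a standard amino acid (3-letter code)."""
    try:
        return KD_HYDROPHOBICITY[resname.upper()]
    except KeyError:
        raise KeyError(f"no Kyte–Doolittle value for residue {resname!r}") from None


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral in degrees, IUPAC convention; NaN for degenerate geometry."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    norm_b1 = np.linalg.norm(b1)
    if norm_b1 < 1e-9:
        return float("nan")
    b1 = b1 / norm_b1
    v = b0 - (b0 @ b1) * b1  # projections into the plane normal to the axis
    w = b2 - (b2 @ b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        return float("nan")
    x = float(v @ w)
    y = float(np.cross(b1, v) @ w)
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


def backbone_dihedrals(structure: Structure) -> dict[ResidueKey, tuple[float, float]]:
    """Backbone (phi, psi) per residue, degrees in (-180, 180].

    First residue of a chain has no phi; last has no psi; either is NaN.
    A peptide-bond distance C(i)–N(i+1) above 2.5 Å is treated as a chain
    break, making both flanking residues termini.  Residues missing backbone
    atoms get NaN for the affected dihedrals.
    """
    result: dict[ResidueKey, tuple[float, float]] = {}
    by_chain: dict[str, list[ResidueKey]] = {}
    for key in structure.residues:
        by_chain.setdefault(key.chain, []).append(key)

    for keys in by_chain.values():
        n = len(keys)
        # bonded[i] — residue i is peptide-bonded to residue i+1
        bonded = []
        for i in range(n - 1):
            c_atom = structure.residues[keys[i]].get_atom("C")
            n_next = structure.residues[keys[i + 1]].get_atom("N")
            bonded.append(
                c_atom is not None
                and n_next is not None
                and np.linalg.norm(c_atom.coord - n_next.coord) <= CHAIN_BREAK_DISTANCE
            )
        for i, key in enumerate(keys):
            residue = structure.residues[key]
            atom_n, atom_ca, atom_c = (residue.get_atom(a) for a in ("N", "CA", "C"))
            phi = psi = float("nan")
            if i > 0 and bonded[i - 1] and None not in (atom_n, atom_ca, atom_c):
                prev_c = structure.residues[keys[i - 1]].get_atom("C")
                if prev_c is not None:
                    phi = _dihedral(prev_c.coord, atom_n.coord, atom_ca.coord, atom_c.coord)
            if i < n - 1 and bonded[i] and None not in (atom_n, atom_ca, atom_c):
                next_n = structure.residues[keys[i + 1]].get_atom("N")
                if next_n is not None:
                    psi = _dihedral(atom_n.coord, atom_ca.coord, atom_c.coord, next_n.coord)
            result[key] = (phi, psi)
    return result


def _fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-spiral)."""
    i = np.arange(n_points)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    vdw_table: dict[str, float] | None = None,
) -> dict[ResidueKey, float]:
    """Solvent-accessible surface area per residue, Å² (Shrake–Rupley).

    Each atom's extended sphere (vdW radius + probe) is sampled on a
    deterministic spherical lattice of ``n_points``; points falling inside
    any neighbouring extended sphere are occluded.  Per-residue areas sum
    the atoms' accessible areas.
    """
    vdw = vdw_table or DEFAULT_VDW
    coords, radii, owner = [], [], []
    for key, residue in structure.residues.items():
        for atom in residue.atoms:
            coords.append(atom.coord)
            radii.append(vdw.get(atom.element.upper(), 1.70) + probe)
            owner.append(key)
    xyz = np.asarray(coords)
    rad = np.asarray(radii)
    sphere = _fibonacci_sphere(n_points)

    tree = cKDTree(xyz)
    neighbors = tree.query_ball_tree(tree, 2.0 * rad.max())
    areas: dict[ResidueKey, float] = {key: 0.0 for key in structure.residues}
    for i in range(len(xyz)):
        points = xyz[i] + rad[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors[i]:
            if j == i:
                continue
            d = np.linalg.norm(points - xyz[j], axis=1)
            accessible &= d > rad[j]
            if not accessible.any():
                break
        frac = accessible.mean()
        areas[owner[i]] += frac * 4.0 * math.pi * rad[i] ** 2
    return areas


def load_gxg_reference() -> dict[str, float]:
    """Reference per-residue surface areas in a Gly-X-Gly tripeptide state, Å²."""
    with importlib.resources.files("fvrin.data").joinpath("gxg_reference.csv").open() as fh:
        table = pd.read_csv(fh)
    return dict(zip(table["resname"], table["reference_area"].astype(float)))


def relative_accessibility(
    area: float, resname: str, reference: dict[str, float] | None = None
) -> float:
    """Residue surface area divided by its Gly-X-Gly reference area."""
    reference = reference or load_gxg_reference()
    ref = reference.get(resname.upper())
    if not ref:
        raise KeyError(f"no (or zero) reference area for residue {resname!r}")
    if area < 0:
        raise ValueError("area must be non-negative")
    return area / ref


def structural_feature_table(
    structure: Structure,
    sesa: pd.Series | dict | None = None,
    sesa_fallback: bool = False,
    probe: float = 1.4,
    n_points: int = 960,
) -> pd.DataFrame:
    """Compute the six structural features for every residue of a structure.

    SESA is an imported column by default (pass per-residue values keyed by
    ResidueKey).  With ``sesa_fallback=True`` and no imported values, a
    probe-0 Shrake–Rupley area is used as a molecular-surface approximation
    and flagged in the ``provenance`` attribute.
    """
    keys = structure.keys()
    accessible = sasa(structure, probe=probe, n_points=n_points)
    dihedrals = backbone_dihedrals(structure)
    reference = load_gxg_reference()

    provenance = {"kd_hydrophobicity": "computed", "sasa": "computed", "phi": "computed", "psi": "computed"}
    if sesa is not None:
        sesa_map = dict(sesa)
        provenance["sesa"] = "imported"
    elif sesa_fallback:
        sesa_map = sasa(structure, probe=0.0, n_points=n_points)
        provenance["sesa"] = "computed (probe-0 approximation)"
    else:
        sesa_map = {}
        provenance["sesa"] = "missing"
    provenance["relative_sesa"] = provenance["sesa"]

    rows = []
    for key in keys:
        resname = structure.residues[key].resname
        kd = KD_HYDROPHOBICITY.get(resname, np.nan)
        area_sesa = sesa_map.get(key, np.nan)
        if np.isfinite(area_sesa) and resname in reference:
            rel = area_sesa / reference[resname]
        else:
            rel = np.nan
        phi, psi = dihedrals.get(key, (np.nan, np.nan))
        rows.append([kd, accessible[key], area_sesa, rel, phi, psi])

    table = pd.DataFrame(
        rows,
        columns=["kd_hydrophobicity", "sasa", "sesa", "relative_sesa", "phi", "psi"],
        index=pd.Index(keys, name="residue", tupleize_cols=False),
    )
    table.attrs["provenance"] = provenance
    return table


def assemble_feature_matrix(
    centralities: pd.DataFrame,
    structural: pd.DataFrame,
    conservation: pd.Series,
    labels: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join all feature sources into the complete 14-feature matrix.

    Rows with any missing feature value or with zero betweenness are dropped
    and itemized in the returned drop log.  Labels referring to residues not
    present in the structure are ignored with a warning.  Returns
    ``(matrix, drop_log)``; ``len(matrix) + len(drop_log)`` equals the input
    residue count.
    """
    merged = structural.join(centralities, how="outer")
    merged["conservation"] = pd.Series(conservation).reindex(merged.index)
    merged = merged.loc[:, list(FEATURE_NAMES)]

    labels = pd.Series(labels).astype(int)
    unknown = labels.index.difference(merged.index)
    if len(unknown) > 0:
        warnings.warn(
            f"{len(unknown)} label(s) refer to residues absent from the structure and are ignored"
        )
    label_col = pd.Series(0, index=merged.index, dtype=int)
    known = labels.index.intersection(merged.index)
    label_col.loc[known] = labels.loc[known].to_numpy()

    reasons = []
    keep = np.ones(len(merged), dtype=bool)
    values = merged.to_numpy(dtype=float)
    missing_mask = ~np.isfinite(values)
    bet = merged["betweenness"].to_numpy(dtype=float)
    for i, key in enumerate(merged.index):
        why = []
        if missing_mask[i].any():
            bad = [merged.columns[j] for j in np.flatnonzero(missing_mask[i])]
            why.append("missing: " + ",".join(bad))
        if np.isfinite(bet[i]) and bet[i] == 0:
            why.append("zero betweenness")
        if why:
            keep[i] = False
            reasons.append((key, "; ".join(why)))

    matrix = merged.loc[keep].copy()
    matrix["label"] = label_col.loc[keep]
    drop_log = pd.DataFrame(reasons, columns=["residue", "reason"]).set_index("residue")
    return matrix, drop_log
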