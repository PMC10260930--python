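"""Structural features: hydropathy, dihedrals, surface areas, matrix assembly."""

import math

import numpy as np
import pandas as pd
import pytest

import fvrin as fv
from fvrin.features import (
    FEATURE_NAMES,
    assemble_feature_matrix,
    backbone_dihedrals,
    kd_hydrophobicity,
    load_gxg_reference,
    relative_accessibility,
    sasa,
    structural_feature_table,
)
from fvrin.structure import Atom, Residue, ResidueKey, Structure


@pytest.mark.parametrize(
    "resname, expected", [("ILE", 4.5), ("ARG", -4.5), ("GLY", -0.4), ("ala", 1.8)]
)
def test_kyte_doolittle_lookup(resname, expected):
    assert kd_hydrophobicity(resname) == expected


def test_unknown_residue_is_named_in_the_error():
    with pytest.raises(KeyError, match="XYZ"):
        kd_hydrophobicity("XYZ")


def test_chain_termini_have_missing_dihedrals(helix12):
    dihedrals = backbone_dihedrals(helix12)
    keys = helix12.keys()
    assert math.isnan(dihedrals[keys[0]][0])  # no phi at the N-terminus
    assert math.isnan(dihedrals[keys[-1]][1])  # no psi at the C-terminus


@pytest.mark.parametrize(
    "torsions", [(-57.0, -47.0), (-120.0, 130.0), (-75.0, 150.0), (55.0, 45.0)]
)
def test_dihedral_round_trip_recovers_requested_torsions(torsions):
    structure = fv.generate_toy_structure(10, torsions=torsions, seed=0)
    dihedrals = backbone_dihedrals(structure)
    keys = structure.keys()
    for key in keys[1:-1]:
        phi, psi = dihedrals[key]
        assert phi == pytest.approx(torsions[0], abs=0.5)
        assert psi == pytest.approx(torsions[1], abs=0.5)


def test_collinear_backbone_gives_missing_dihedral():
    structure = Structure()
    # two residues whose N-CA-C atoms all lie on the x axis
    for i in range(2):
        x = 3.0 * i
        structure.residues[ResidueKey("A", i + 1, "")] = Residue(
            "GLY",
            [
                Atom("N", "N", np.array([x, 0.0, 0.0])),
                Atom("CA", "C", np.array([x + 1.0, 0.0, 0.0])),
                Atom("C", "C", np.array([x + 2.0, 0.0, 0.0])),
            ],
        )
    dihedrals = backbone_dihedrals(structure)
    assert math.isnan(dihedrals[ResidueKey("A", 2, "")][0])


def test_chain_break_treated_as_termini():
    helix = fv.generate_toy_structure(6)
    far = fv.generate_toy_structure(6)
    combined = Structure()
    for key, res in helix.residues.items():
        combined.residues[key] = res
    for key, res in far.residues.items():
        shifted = [Atom(a.name, a.element, a.coord + 100.0) for a in res.atoms]
        combined.residues[ResidueKey("A", key.seqnum + 6, "")] = Residue(res.resname, shifted)
    dihedrals = backbone_dihedrals(combined)
    assert math.isnan(dihedrals[ResidueKey("A", 6, "")][1])  # psi before the break
    assert math.isnan(dihedrals[ResidueKey("A", 7, "")][0])  # phi after the break


def isolated_atom_structure(element="C", n=1, spacing=100.0):
    structure = Structure()
    for i in range(n):
        structure.residues[ResidueKey("A", i + 1, "")] = Residue(
            "GLY", [Atom("CA", element, np.array([spacing * i, 0.0, 0.0]))]
        )
    return structure


def test_sasa_of_isolated_carbon_is_the_sphere_area():
    areas = sasa(isolated_atom_structure())
    expected = 4.0 * math.pi * (1.70 + 1.4) ** 2  # ~120.76
    assert areas[ResidueKey("A", 1, "")] == pytest.approx(expected, rel=0.01)


def test_sasa_distant_atoms_do_not_occlude():
    areas = sasa(isolated_atom_structure(n=2, spacing=100.0))
    expected = 4.0 * math.pi * (1.70 + 1.4) ** 2
    for area in areas.values():
        assert area == pytest.approx(expected, rel=0.01)


def test_sasa_of_caged_atom_is_near_zero():
    structure = Structure()
    structure.residues[ResidueKey("A", 1, "")] = Residue(
        "GLY", [Atom("CA", "C", np.zeros(3))]
    )
    # dense cage of atoms on a sphere of radius 3 Å fully encloses the center
    cage_points = []
    for theta in np.linspace(0, math.pi, 12):
        for phi in np.linspace(0, 2 * math.pi, 24, endpoint=False):
            cage_points.append(
                3.0
                * np.array(
                    [
                        math.sin(theta) * math.cos(phi),
                        math.sin(theta) * math.sin(phi),
                        math.cos(theta),
                    ]
                )
            )
    structure.residues[ResidueKey("B", 1, "")] = Residue(
        "GLY", [Atom("CA", "C", p) for p in cage_points]
    )
    areas = sasa(structure)
    assert areas[ResidueKey("A", 1, "")] == pytest.approx(0.0, abs=1.0)


def test_sasa_converges_with_point_density(helix12):
    coarse = sasa(helix12, n_points=960)
    fine = sasa(helix12, n_points=1920)
    for key in helix12.keys():
        assert fine[key] == pytest.approx(coarse[key], rel=0.02)


def test_relative_accessibility_arithmetic():
    reference = load_gxg_reference()
    assert relative_accessibility(reference["GLY"], "GLY") == pytest.approx(1.0)
    assert relative_accessibility(0.0, "TRP") == 0.0
    assert relative_accessibility(40.0, "GLY") == pytest.approx(40.0 / reference["GLY"])
    with pytest.raises(KeyError):
        relative_accessibility(10.0, "UNK")


def synthetic_sources(n=30, seed=0):
    rng = np.random.default_rng(seed)
    keys = [ResidueKey("A", i + 1, "") for i in range(n)]
    index = pd.Index(keys, name="residue", tupleize_cols=False)
    cent = pd.DataFrame(
        {
            "degree": rng.integers(1, 10, n).astype(float),
            "betweenness": rng.uniform(1, 100, n),
            "closeness": rng.random(n),
            "kcore": rng.integers(1, 4, n).astype(float),
            "burts_constraint": rng.random(n),
            "authority": rng.random(n),
            "pagerank": rng.random(n),
        },
        index=index,
    )
    struct = pd.DataFrame(
        {
            "kd_hydrophobicity": rng.uniform(-4.5, 4.5, n),
            "sasa": rng.uniform(0, 200, n),
            "sesa": rng.uniform(0, 200, n),
            "relative_sesa": rng.random(n),
            "phi": rng.uniform(-180, 180, n),
            "psi": rng.uniform(-180, 180, n),
        },
        index=index,
    )
    conservation = pd.Series(rng.uniform(1, 9, n), index=index)
    labels = pd.Series(1, index=index[:5])
    return cent, struct, conservation, labels


def test_assembly_keeps_complete_rows_and_counts_balance():
    cent, struct, conservation, labels = synthetic_sources()
    matrix, dropped = assemble_feature_matrix(cent, struct, conservation, labels)
    assert len(matrix) + len(dropped) == len(cent)
    assert len(dropped) == 0
    assert list(matrix.columns) == list(FEATURE_NAMES) + ["label"]
    assert matrix["label"].sum() == 5


def test_assembly_drops_zero_betweenness_and_missing_values():
    cent, struct, conservation, labels = synthetic_sources()
    cent.iloc[0, cent.columns.get_loc("betweenness")] = 0.0
    struct.iloc[1, struct.columns.get_loc("phi")] = np.nan
    matrix, dropped = assemble_feature_matrix(cent, struct, conservation, labels)
    assert len(matrix) == len(cent) - 2
    reasons = dropped["reason"].str.cat()
    assert "zero betweenness" in reasons and "phi" in reasons


def test_label_for_unknown_residue_warns_and_is_ignored():
    cent, struct, conservation, labels = synthetic_sources()
    labels = pd.concat(
        [labels, pd.Series([1], index=[ResidueKey("Z", 999, "")])]
    )
    with pytest.warns(UserWarning, match="absent"):
        matrix, _ = assemble_feature_matrix(cent, struct, conservation, labels)
    assert matrix["label"].sum() == 5


def test_structural_table_has_the_six_features(helix12):
    table = structural_feature_table(helix12, sesa_fallback=True, n_points=240)
    assert list(table.columns) == list(FEATURE_NAMES[:6])
    assert table["sasa"].gt(0).all()
    assert table.attrs["provenance"]["sesa"].startswith("computed")
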