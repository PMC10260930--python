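"""Parsing and writing of protein structures in PDB format.

The internal model is deliberately small: a :class:`Structure` is an ordered
map from :class:`ResidueKey` (chain, author sequence number, insertion code)
to a residue name plus its atoms.  Only amino-acid residues are kept —
ligands, waters and other heteroatoms are outside the scope of a residue
interaction network.  Author (PDB) numbering is authoritative throughout;
no renumbering to a mature-chain frame is ever applied.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

__all__ = [
    "Atom",
    "ResidueKey",
    "Residue",
    "Structure",
    "StructureParseError",
    "parse_structure",
    "write_structure",
    "BACKBONE_ATOMS",
    "NONSTANDARD_PARENT",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Non-standard residues mapped onto a standard parent amino acid.
#: Editable: callers may pass an extended table to :func:`parse_structure`.
NONSTANDARD_PARENT = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",
    "PYL": "LYS",
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
}

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class StructureParseError(ValueError):
    """Raised when a PDB text cannot be turned into a Structure."""


class ResidueKey(NamedTuple):
    """Identity of a residue: (chain id, author seq number, insertion code)."""

    chain: str
    seqnum: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:123" or "A:123B"
        return f"{self.chain}:{self.seqnum}{self.icode}"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coord", coord)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    resname: str
    atoms: list[Atom] = field(default_factory=list)

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None


@dataclass
class Structure:
    """Ordered residues of one model of a structure."""

    residues: dict[ResidueKey, Residue] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[ResidueKey]:
        return iter(self.residues)

    def keys(self) -> list[ResidueKey]:
        return list(self.residues)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for key in self.residues:
            seen.setdefault(key.chain, None)
        return list(seen)


def _validate_coordinates(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except (ValueError, IndexError):
                raise StructureParseError(
                    f"malformed coordinates on line {lineno}: {line.rstrip()!r}"
                ) from None


def parse_structure(
    pdb_text: str,
    model_index: int = 0,
    altloc_policy: str = "highest_occupancy",
    nonstandard: dict[str, str] | None = None,
) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Parameters
    ----------
    pdb_text:
        Full text of a PDB file (must contain at least one ATOM record).
    model_index:
        Which MODEL to keep (0-based position in file order).
    altloc_policy:
        ``"highest_occupancy"`` keeps, per alternate-location group, the atom
        with the highest occupancy (ties broken by file order); ``"first"``
        keeps the first atom of each group.
    nonstandard:
        Mapping of non-standard residue names to a standard parent amino
        acid; defaults to :data:`NONSTANDARD_PARENT`.
    """
    if altloc_policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    table = NONSTANDARD_PARENT if nonstandard is None else nonstandard
    if "ATOM" not in pdb_text:
        raise StructureParseError("no ATOM records found")
    _validate_coordinates(pdb_text)

    parser = PDBParser(QUIET=True)
    bio_structure = parser.get_structure("structure", io.StringIO(pdb_text))
    models = list(bio_structure.get_models())
    if not models:
        raise StructureParseError("no models found")
    if model_index >= len(models):
        raise StructureParseError(
            f"model index {model_index} out of range (file has {len(models)} model(s))"
        )
    model = models[model_index]

    structure = Structure()
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            if resname in table:
                resname = table[resname]
            if resname not in STANDARD_AA and not is_aa(residue, standard=True):
                continue  # ligands, waters, ions
            hetfield, seqnum, icode = residue.get_id()
            key = ResidueKey(chain.id, int(seqnum), icode.strip())
            atoms: list[Atom] = []
            # group alternate locations by atom name and apply the policy
            groups: dict[str, list] = {}
            for bio_atom in residue.get_unpacked_list():
                groups.setdefault(bio_atom.get_name(), []).append(bio_atom)
            for name, group in groups.items():
                if altloc_policy == "highest_occupancy":
                    # max is stable: ties go to the first atom in file order
                    chosen = max(group, key=lambda a: a.get_occupancy() or 0.0)
                else:
                    chosen = group[0]
                occupancy = chosen.get_occupancy()
                atoms.append(
                    Atom(
                        name=name,
                        element=(chosen.element or "").strip().upper() or name[0],
                        coord=np.asarray(chosen.get_coord(), dtype=float),
                        occupancy=1.0 if occupancy is None else min(float(occupancy), 1.0),
                        altloc=chosen.get_altloc().strip(),
                    )
                )
            if atoms:
                if key in structure.residues:
                    warnings.warn(f"duplicate residue {key}; keeping first occurrence")
                    continue
                structure.residues[key] = Residue(resname=resname, atoms=atoms)

    if not structure.residues:
        raise StructureParseError("model contains no amino-acid residues")
    return structure


def write_structure(structure: Structure) -> str:
    """Serialize a Structure as minimal fixed-column PDB ATOM records."""
    lines: list[str] = []
    serial = 1
    previous_chain: str | None = None
    for key, residue in structure.residues.items():
        if previous_chain is not None and key.chain != previous_chain:
            lines.append("TER")
        previous_chain = key.chain
        for atom in residue.atoms:
            name = atom.name
            # PDB convention: 1-char element symbols start in column 14
            padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:>5d} {padded}{'':1s}{residue.resname:>3s} "
                f"{key.chain:1s}{key.seqnum:>4d}{key.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
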