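"""Residue interaction network (RIN) construction.

Two residues are connected when any pair of their atoms is close enough for
a small solvent probe rolled over the van der Waals surfaces to touch both:
``dist(a, b) <= vdw(a) + vdw(b) + 2 * probe_radius``.  This atom-pair
distance criterion is the first-order approximation of two vdW surfaces
bridged by a rolling probe; it is deterministic and testable by brute force.
The resulting graph is simple (no self-loops, no parallel edges), undirected
and unweighted; each edge carries a contact-category annotation — SS
(side-chain/side-chain), MM (main-chain/main-chain) or SM (mixed) — taken
from the closest qualifying atom pair.  The annotation is metadata only; the
downstream analysis uses the unweighted simple graph.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import IO

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure import ResidueKey, Structure

__all__ = ["ContactRule", "build_rin", "simplify_graph", "write_edge_table", "write_sif", "DEFAULT_VDW"]

#: Default heavy-atom van der Waals radii, Å (Bondi-style; editable).
DEFAULT_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20, "SE": 1.90}


@dataclass
class ContactRule:
    """Parameters of the probe-mediated atomic contact criterion.

    ``min_seq_separation=1`` excludes only a residue's contact with itself;
    sequence-adjacent residues (|i - j| = 1) therefore remain as edges.
    With ``heavy_atoms_only`` (the default) hydrogens are ignored and the
    slightly generous heavy-atom radii compensate for the missing protons,
    which removes any dependency on protonation software.
    """

    probe_radius: float = 0.25
    vdw_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW))
    min_seq_separation: int = 1
    heavy_atoms_only: bool = True

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if any(r <= 0 for r in self.vdw_table.values()):
            raise ValueError("all vdW radii must be positive")

    def radius_of(self, element: str) -> float:
        return self.vdw_table.get(element.upper(), self.vdw_table.get("C", 1.70))


def build_rin(structure: Structure, rule: ContactRule | None = None) -> nx.Graph:
    """Build the residue interaction network of a structure.

    Returns a simple undirected :class:`networkx.Graph` whose nodes are
    :class:`~fvrin.structure.ResidueKey` and whose edges carry a ``kind``
    attribute in ``{"SS", "SM", "MM"}``.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    rule = rule or ContactRule()

    graph: nx.Graph = nx.Graph()
    coords: list[np.ndarray] = []
    radii: list[float] = []
    owner: list[ResidueKey] = []
    backbone: list[bool] = []
    for key, residue in structure.residues.items():
        graph.add_node(key, resname=residue.resname)
        usable = 0
        for atom in residue.atoms:
            if rule.heavy_atoms_only and atom.element in ("H", "D"):
                continue
            coords.append(atom.coord)
            radii.append(rule.radius_of(atom.element))
            owner.append(key)
            backbone.append(atom.is_backbone)
            usable += 1
        if usable == 0:
            warnings.warn(f"residue {key} has no usable atoms under the contact rule; kept isolated")

    if not coords:
        return graph
    xyz = np.asarray(coords)
    rad = np.asarray(radii)
    cutoff = 2.0 * rad.max() + 2.0 * rule.probe_radius

    tree = cKDTree(xyz)
    # closest qualifying pair per residue pair, ranked by surface gap
    best_gap: dict[tuple[ResidueKey, ResidueKey], tuple[float, str]] = {}
    for i, j in tree.query_pairs(cutoff):
        ki, kj = owner[i], owner[j]
        if ki == kj:
            continue
        if ki.chain == kj.chain and abs(ki.seqnum - kj.seqnum) < rule.min_seq_separation:
            continue
        dist = float(np.linalg.norm(xyz[i] - xyz[j]))
        threshold = rad[i] + rad[j] + 2.0 * rule.probe_radius
        if dist > threshold:
            continue
        gap = dist - rad[i] - rad[j]
        if backbone[i] and backbone[j]:
            kind = "MM"
        elif backbone[i] or backbone[j]:
            kind = "SM"
        else:
            kind = "SS"
        edge = (ki, kj) if ki <= kj else (kj, ki)
        if edge not in best_gap or gap < best_gap[edge][0]:
            best_gap[edge] = (gap, kind)

    for (ki, kj), (_, kind) in best_gap.items():
        graph.add_edge(ki, kj, kind=kind)
    return simplify_graph(graph)


def simplify_graph(graph: nx.Graph) -> nx.Graph:
    """Remove self-loops and parallel edges; idempotent; node set preserved."""
    simple: nx.Graph = nx.Graph()
    simple.add_nodes_from(graph.nodes(data=True))
    for u, v, data in graph.edges(data=True):
        if u == v:
            continue
        if not simple.has_edge(u, v):
            simple.add_edge(u, v, **data)
    return simple


def write_edge_table(graph: nx.Graph, handle: IO[str]) -> None:
    """Write edges as CSV: chain_i,seq_i,icode_i,chain_j,seq_j,icode_j,kind."""
    writer = csv.writer(handle, lineterminator="\n")
    writer.writerow(["chain_i", "seq_i", "icode_i", "chain_j", "seq_j", "icode_j", "kind"])
    for u, v, data in sorted(graph.edges(data=True)):
        writer.writerow([u.chain, u.seqnum, u.icode, v.chain, v.seqnum, v.icode, data.get("kind", "")])


def write_sif(graph: nx.Graph, handle: IO[str]) -> None:
    """SIF export for external network viewers (one edge per line)."""
    for u, v, data in sorted(graph.edges(data=True)):
        handle.write(f"{u}\t{data.get('kind', 'contact')}\t{v}\n")
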