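"""Criticality classification of residues.

Two complementary views of residue importance:

* **Bin labels.**  The (degree, log10 betweenness) plane is divided into
  4 uniform bins per axis spanning the observed range.  The three named
  corners are HDHB (top degree bin and top log-betweenness bin), LDHB
  (bottom degree, top log-betweenness) and LDLB (bottom degree, bottom
  log-betweenness); every other combination is UNCLASSIFIED.  Bins are
  half-open ``(lo, hi]`` with the lowest edge nudged down by 0.1% of the
  axis range so the minimum value lands inside the first bin.  Nodes with
  zero betweenness cannot be placed on the log axis and are excluded
  (labelled UNCLASSIFIED), mirroring the feature-matrix discard rule.

* **Supercritical set.**  The Pareto front of (degree, betweenness,
  closeness) under maximization: residues not strictly dominated by any
  other residue.  Weak-dominance convention — all non-dominated ties are
  kept.  The front is invariant under any strictly monotone transform of
  any axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = ["BinGrid", "CriticalityClass", "bin_criticality", "pareto_supercritical", "criticality_table"]

EDGE_NUDGE_FRACTION = 1e-3


class CriticalityClass(str, Enum):
    HDHB = "HDHB"
    LDHB = "LDHB"
    LDLB = "LDLB"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class BinGrid:
    """Uniform 4-bin edges on the degree and log10-betweenness axes.

    Edges are ascending; bins are half-open ``(edges[i], edges[i+1]]`` and
    the lowest edge has been nudged down so the axis minimum is included.
    """

    degree_edges: tuple[float, ...]
    logbet_edges: tuple[float, ...]
    n_bins: int = 4


def _uniform_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if np.unique(values).size < 2:
        raise ValueError("axis has fewer than 2 distinct values; bins are degenerate")
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[0] -= EDGE_NUDGE_FRACTION * (hi - lo)
    return edges


def _assign(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open (lo, hi] bin index; values on an edge fall in the lower bin."""
    idx = np.searchsorted(edges, values, side="left") - 1
    return np.clip(idx, 0, len(edges) - 2)


def bin_criticality(
    table: pd.DataFrame, n_bins: int = 4
) -> tuple[pd.Series, BinGrid]:
    """Label residues HDHB / LDHB / LDLB / UNCLASSIFIED.

    ``table`` needs ``degree`` and ``betweenness`` columns (one row per
    residue).  Returns the label Series (aligned with ``table.index``) and
    the :class:`BinGrid` used.
    """
    degree = table["degree"].to_numpy(dtype=float)
    betweenness = table["betweenness"].to_numpy(dtype=float)
    included = betweenness > 0
    if included.sum() < 2:
        raise ValueError("fewer than 2 nodes with positive betweenness")

    deg_in = degree[included]
    logbet_in = np.log10(betweenness[included])
    deg_edges = _uniform_edges(deg_in, n_bins)
    lb_edges = _uniform_edges(logbet_in, n_bins)

    deg_bin = _assign(deg_in, deg_edges)
    lb_bin = _assign(logbet_in, lb_edges)
    top = n_bins - 1

    labels = np.full(len(table), CriticalityClass.UNCLASSIFIED.value, dtype=object)
    inner = np.full(included.sum(), CriticalityClass.UNCLASSIFIED.value, dtype=object)
    inner[(deg_bin == top) & (lb_bin == top)] = CriticalityClass.HDHB.value
    inner[(deg_bin == 0) & (lb_bin == top)] = CriticalityClass.LDHB.value
    inner[(deg_bin == 0) & (lb_bin == 0)] = CriticalityClass.LDLB.value
    labels[included] = inner

    grid = BinGrid(tuple(deg_edges.tolist()), tuple(lb_edges.tolist()), n_bins)
    return pd.Series(labels, index=table.index, name="criticality"), grid


def pareto_supercritical(
    table: pd.DataFrame,
    objectives: tuple[str, str, str] = ("degree", "betweenness", "closeness"),
) -> set:
    """Residues on the Pareto front maximizing the three objectives.

    x dominates y iff x >= y on every objective and x > y on at least one.
    """
    if len(table) == 0:
        raise ValueError("empty centrality table")
    points = table.loc[:, list(objectives)].to_numpy(dtype=float)
    # sort lexicographically descending: a dominator always precedes the
    # points it dominates, so each point need only be tested against the
    # current front
    order = np.lexsort(points.T[::-1])[::-1]
    front_rows: list[int] = []
    front_pts = np.empty((0, points.shape[1]))
    for row in order:
        p = points[row]
        dominated = np.any(np.all(front_pts >= p, axis=1) & np.any(front_pts > p, axis=1))
        if not dominated:
            front_rows.append(row)
            front_pts = np.vstack([front_pts, p])
    return {table.index[i] for i in front_rows}


def criticality_table(centralities: pd.DataFrame, n_bins: int = 4) -> tuple[pd.DataFrame, BinGrid]:
    """Combined per-residue report: bins, log-betweenness and the supercritical flag."""
    labels, grid = bin_criticality(centralities, n_bins)
    front = pareto_supercritical(centralities)
    betweenness = centralities["betweenness"].to_numpy(dtype=float)
    report = pd.DataFrame(
        {
            "degree": centralities["degree"],
            "log10_betweenness": np.where(betweenness > 0, np.log10(np.where(betweenness > 0, betweenness, 1.0)), np.nan),
            "criticality": labels,
            "supercritical": [key in front for key in centralities.index],
        },
        index=centralities.index,
    )
    return report, grid
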