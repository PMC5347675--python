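"""Drug-gene network construction and scale-free topology diagnostics.

A drug node is linked to its directly associated genes (FAGs, e.g. from
curated pharmacogenomic databases); protein-interaction neighbors of FAGs
are recruited as indirectly associated genes (IAGs). Only interaction edges
incident to a FAG are retained, so the network is the first-neighborhood of
the FAG set — a near-tree, as expected when neighbors are recruited without
closing triangles among them.

Diagnostics are those used to argue a network is scale-free: per-node
topological coefficients and pair-normalized betweenness centrality,
averaged by degree and fitted with a power law y = a * x^b by least squares
on the log-log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "DrugGeneNetwork",
    "PowerLawFit",
    "build_network",
    "topological_coefficient",
    "betweenness_centrality",
    "fit_power_law",
    "degree_profile",
    "load_associations",
    "load_ppi_edges",
    "node_attribute_table",
]


@dataclass(frozen=True)
class DrugGeneNetwork:
    """Simple undirected graph of one drug, its FAGs and their IAG neighbors."""

    drug_node: str
    fag_nodes: frozenset[str]
    iag_nodes: frozenset[str]
    graph: nx.Graph

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


@dataclass(frozen=True)
class PowerLawFit:
    """y = coefficient * x**exponent, with R^2 on the fitted (log) scale."""

    coefficient: float
    exponent: float
    r_squared: float


def _norm(symbol: str) -> str:
    return " ".join(str(symbol).split()).upper()


def build_network(
    drug: str,
    fags: Iterable[str],
    ppi_edges: Iterable[tuple[str, str]],
) -> DrugGeneNetwork:
    """Assemble the drug-centered first-neighbor network.

    Nodes are the drug, the FAGs, and every PPI partner of a FAG. Edges are
    drug-FAG edges plus each PPI edge having at least one FAG endpoint
    (IAG-IAG edges are not recruited). Self-loops and duplicate edges are
    collapsed; direction in the source edge list is ignored.
    """
    drug_node = _norm(drug)
    fag_set = frozenset(_norm(g) for g in fags if _norm(g))
    if not fag_set:
        raise ValueError("FAG list is empty; cannot build a drug-gene network")
    if drug_node in fag_set:
        raise ValueError("drug identifier collides with a gene symbol")
    g = nx.Graph()
    g.add_node(drug_node)
    for fag in fag_set:
        g.add_edge(drug_node, fag)
    for u, v in ppi_edges:
        u, v = _norm(u), _norm(v)
        if not u or not v or u == v:
            continue
        if u in fag_set or v in fag_set:
            g.add_edge(u, v)
    iag_set = frozenset(set(g.nodes) - fag_set - {drug_node})
    return DrugGeneNetwork(drug_node, fag_set, iag_set, g)


def _graph(network: DrugGeneNetwork | nx.Graph) -> nx.Graph:
    return network.graph if isinstance(network, DrugGeneNetwork) else network


def topological_coefficient(
    network: DrugGeneNetwork | nx.Graph, node
) -> float | None:
    """Shared-neighbor topological coefficient of one node.

    TC(n) = mean_m J(n, m) / degree(n), the mean running over every node
    m != n that shares at least one neighbor with n, where J(n, m) is the
    number of shared neighbors plus one if n and m are adjacent. ``None``
    (undefined) for isolated nodes and nodes with no qualifying partner m.
    """
    g = _graph(network)
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    nbrs = set(g[node])
    k = len(nbrs)
    if k == 0:
        return None
    candidates = set()
    for w in nbrs:
        candidates.update(g[w])
    candidates.discard(node)
    j_values = []
    for m in candidates:
        shared = len(nbrs & set(g[m]))
        if shared == 0:
            continue
        j_values.append(shared + (1 if g.has_edge(node, m) else 0))
    if not j_values:
        return None
    return (sum(j_values) / len(j_values)) / k


def betweenness_centrality(
    network: DrugGeneNetwork | nx.Graph,
) -> dict:
    """Shortest-path betweenness, pair-normalized by 2/((N-1)(N-2)).

    Disconnected graphs are accepted; graphs with fewer than three nodes
    have no mediated pairs and return all zeros.
    """
    g = _graph(network)
    if g.number_of_nodes() < 3:
        return {v: 0.0 for v in g}
    return nx.betweenness_centrality(g, normalized=True)


def fit_power_law(points: Sequence[tuple[float, float]]) -> PowerLawFit:
    """Least-squares power-law fit y = a * x^b on the log-log scale.

    Points with y <= 0 are excluded before fitting (x must be positive).
    R^2 is the coefficient of determination of the line on (ln x, ln y);
    a constant-y input fits a zero-slope line exactly and reports R^2 = 1.
    """
    usable = [(x, y) for x, y in points if y > 0]
    if any(x <= 0 for x, _ in usable):
        raise ValueError("x values must be positive")
    xs = np.log([x for x, _ in usable])
    ys = np.log([y for _, y in usable])
    if len(set(xs.tolist())) < 2:
        raise ValueError("need at least 2 points with distinct x to fit")
    slope, intercept = np.polyfit(xs, ys, 1)
    residuals = ys - (slope * xs + intercept)
    ss_res = float(residuals @ residuals)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(float(math.exp(intercept)), float(slope), min(max(r2, 0.0), 1.0))


def degree_profile(
    network: DrugGeneNetwork | nx.Graph,
    metric: str,
) -> list[tuple[int, float]]:
    """Per-degree mean of a node metric, for log-log scatter/fitting.

    ``metric`` is ``"tc"`` (topological coefficient) or ``"betweenness"``.
    Nodes whose metric is undefined are dropped; degrees with no surviving
    node yield no pair. Zero-mean pairs are retained here and excluded by
    :func:`fit_power_law` itself.
    """
    g = _graph(network)
    if metric == "tc":
        values = {v: topological_coefficient(g, v) for v in g}
    elif metric == "betweenness":
        values = dict(betweenness_centrality(g))
    else:
        raise ValueError(f"unknown metric {metric!r}; expected 'tc' or 'betweenness'")
    by_degree: dict[int, list[float]] = {}
    for v, val in values.items():
        if val is None:
            continue
        by_degree.setdefault(g.degree(v), []).append(val)
    return sorted((d, sum(vs) / len(vs)) for d, vs in by_degree.items())


# ---------------------------------------------------------------------------
# file interfaces (2-column TSVs emulating curated database exports)


def load_associations(path) -> dict[str, set[str]]:
    """Read a drug->gene association TSV (drug, gene[, evidence...])."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}: malformed association at line {lineno}")
            out.setdefault(_norm(parts[0]), set()).add(_norm(parts[1]))
    return out


def load_ppi_edges(path) -> list[tuple[str, str]]:
    """Read a gene-gene interaction TSV (two gene-symbol columns)."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}: malformed interaction at line {lineno}")
            edges.append((_norm(parts[0]), _norm(parts[1])))
    return edges


def node_attribute_table(network: DrugGeneNetwork):
    """Per-node role/degree/TC/betweenness as a DataFrame (export surface)."""
    import pandas as pd

    bc = betweenness_centrality(network)
    rows = []
    for v in sorted(network.graph.nodes):
        role = (
            "drug"
            if v == network.drug_node
            else "FAG" if v in network.fag_nodes else "IAG"
        )
        tc = topological_coefficient(network, v)
        rows.append(
            {
                "node": v,
                "role": role,
                "degree": network.graph.degree(v),
                "tc": "" if tc is None else tc,
                "betweenness": bc[v],
            }
        )
    return pd.DataFrame.from_records(
        rows, columns=["node", "role", "degree", "tc", "betweenness"]
    )
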