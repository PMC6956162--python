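"""Data-driven topological filtering via orthogonal minimal spanning trees.

Edge-disjoint minimum spanning trees (distance = 1/weight, so an MST is the
maximum-weight backbone) are extracted iteratively; after adding the m-th
tree the objective ``J_m = GE_m - Cost_m`` is evaluated, where GE is the
global efficiency of the selected union (mean inverse shortest-path
distance over all node pairs) and Cost is the selected weight divided by
the total weight of the graph.  The union with the highest objective is the
filtered graph.  On a disconnected graph the extraction runs per connected
component and GE treats unreachable pairs as zero efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np


def _to_graph(w: np.ndarray) -> nx.Graph:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(np.diag(w) != 0):
        raise ValueError("weight matrix must have a zero diagonal")
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    for i in range(w.shape[0]):
        for j in range(i + 1, w.shape[0]):
            if w[i, j] > 0:
                g.add_edge(i, j, weight=w[i, j], distance=1.0 / w[i, j])
    return g


def mst(w: np.ndarray | nx.Graph) -> list[tuple[int, int]]:
    """Minimum spanning tree on distances 1/w (= maximum-weight tree).

    Raises on a disconnected graph, naming the components.
    """
    g = w if isinstance(w, nx.Graph) else _to_graph(w)
    if g.number_of_nodes() == 0:
        return []
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValueError(f"graph is disconnected; components: {comps}")
    edges = nx.minimum_spanning_edges(g, weight="distance", data=False)
    return [tuple(sorted(e)) for e in edges]


def global_efficiency(w: np.ndarray) -> float:
    """Mean inverse shortest-path distance (d = 1/w) over all node pairs."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if n < 2:
        return 0.0
    g = _to_graph(w)
    eff = 0.0
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="distance"))
    for i in range(n):
        row = lengths.get(i, {})
        for j in range(i + 1, n):
            d = row.get(j, np.inf)
            if d > 0 and np.isfinite(d):
                eff += 1.0 / d
    return eff / (n * (n - 1) / 2)


@dataclass
class OmstInfo:
    """Audit trail of the OMST extraction."""

    n_trees_extracted: int
    n_trees_selected: int
    objective: list[float]       # J_m after each extraction round
    cost: list[float]
    efficiency: list[float]
    trees: list[list[tuple[int, int]]]


def omst_filter(w: np.ndarray) -> tuple[np.ndarray, OmstInfo]:
    """Orthogonal-MST filtering of a weighted graph.

    Returns the filtered weight matrix (union of the selected edge-disjoint
    spanning trees/forests) and an :class:`OmstInfo` audit record.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    total_weight = w[np.triu_indices(n, 1)].sum()
    if total_weight <= 0:
        return np.zeros_like(w), OmstInfo(0, 0, [], [], [], [])
    remaining = w.copy()
    selected = np.zeros_like(w)
    trees: list[list[tuple[int, int]]] = []
    objective: list[float] = []
    costs: list[float] = []
    effs: list[float] = []
    # components of the *original* graph: each extracted tree must span its
    # component; once the remaining edges cannot, that component is done
    base_components = [
        comp for comp in nx.connected_components(_to_graph(w)) if len(comp) > 1
    ]
    while True:
        g = _to_graph(remaining)
        round_edges: list[tuple[int, int]] = []
        for comp in base_components:
            sub = g.subgraph(comp)
            if sub.number_of_edges() < len(comp) - 1 or not nx.is_connected(sub):
                continue
            tree_edges = nx.minimum_spanning_edges(sub, weight="distance",
                                                   data=False)
            round_edges.extend(tuple(sorted(e)) for e in tree_edges)
        if not round_edges:
            break
        for i, j in round_edges:
            selected[i, j] = selected[j, i] = w[i, j]
            remaining[i, j] = remaining[j, i] = 0.0
        trees.append(sorted(round_edges))
        cost = selected[np.triu_indices(n, 1)].sum() / total_weight
        eff = global_efficiency(selected)
        costs.append(cost)
        effs.append(eff)
        objective.append(eff - cost)
    if not objective:
        return np.zeros_like(w), OmstInfo(0, 0, [], [], [], [])
    m_best = int(np.argmax(objective)) + 1
    filtered = np.zeros_like(w)
    for tree in trees[:m_best]:
        for i, j in tree:
            filtered[i, j] = filtered[j, i] = w[i, j]
    return filtered, OmstInfo(
        n_trees_extracted=len(trees),
        n_trees_selected=m_best,
        objective=objective,
        cost=costs,
        efficiency=effs,
        trees=trees,
    )
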