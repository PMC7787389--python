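"""Distance-graph skeletonization via iterated edge-disjoint minimum
spanning trees, with a structural-dissimilarity convergence diagnostic.

Each iteration extracts the minimum spanning tree of the working graph,
records it, and removes its edges before the next iteration, so the trees
are pairwise edge-disjoint and aggregating the first ``m`` of them on a
connected ``n``-node graph yields exactly ``m * (n - 1)`` edges. The
dissimilarity between consecutive trees is quantified by a [0, 1] D-value
combining (i) the Jensen-Shannon divergence of the graphs' averaged
node-distance distributions, (ii) the difference of square-rooted network
node dispersions, and (iii) an alpha-centrality term on the graphs and
their complements, with weights 0.45 / 0.45 / 0.10.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from isonymica.isonymy import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SkeletonRun",
    "mmst",
    "schieber_d",
    "choose_depth",
    "network_stats",
    "skeleton_walk",
    "write_skeleton",
    "write_d_series",
]

_LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# structural dissimilarity (D-value)
# ---------------------------------------------------------------------------

def _distance_profiles(graph: nx.Graph) -> tuple[np.ndarray, int]:
    """Per-node distance distributions.

    Row i holds the fraction of other nodes at hop distance 1..(n-1) from
    node i, followed by one dedicated bin for unreachable pairs. Also
    returns the effective diameter: the largest finite distance, plus one
    if any pair is unreachable.
    """
    n = graph.number_of_nodes()
    nodes = sorted(graph.nodes, key=str)
    if n == 1:
        return np.zeros((1, 1)), 0
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr")
    dist = shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)
    profiles = np.zeros((n, n))  # bins: distance 1..n-1, then unreachable
    finite_max = 0
    for i in range(n):
        row = dist[i]
        for j in range(n):
            if i == j:
                continue
            d = row[j]
            if math.isinf(d):
                profiles[i, n - 1] += 1
            else:
                d = int(d)
                profiles[i, d - 1] += 1
                finite_max = max(finite_max, d)
    profiles /= n - 1
    d_eff = finite_max + (1 if profiles[:, n - 1].any() else 0)
    return profiles, d_eff


def _align(mu_a: np.ndarray, mu_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pad two (finite-bins..., unreachable) vectors to a common length,
    keeping the unreachable bins aligned at the end."""
    la, lb = len(mu_a) - 1, len(mu_b) - 1
    width = max(la, lb)
    out_a = np.zeros(width + 1)
    out_b = np.zeros(width + 1)
    out_a[:la] = mu_a[:la]
    out_a[-1] = mu_a[-1]
    out_b[:lb] = mu_b[:lb]
    out_b[-1] = mu_b[-1]
    return out_a, out_b


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence with natural logarithms."""
    m = (p + q) / 2.0
    def kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / m[mask])))
    return 0.5 * kl(p) + 0.5 * kl(q)


def _node_dispersion(profiles: np.ndarray, d_eff: int) -> float:
    """Jensen-Shannon divergence among the node distance distributions,
    normalized by log(d_eff + 1)."""
    if d_eff == 0:
        return 0.0
    n = profiles.shape[0]
    mu = profiles.mean(axis=0)
    total = 0.0
    for i in range(n):
        p = profiles[i]
        mask = p > 0
        total += float(np.sum(p[mask] * np.log(p[mask] / mu[mask])))
    return (total / n) / math.log(d_eff + 1)


def _alpha_centrality_dist(graph: nx.Graph) -> np.ndarray:
    """Normalized Bonacich alpha-centrality vector (alpha = 1/n), sorted
    descending. Strictly positive because alpha is below 1/spectral radius."""
    n = graph.number_of_nodes()
    nodes = sorted(graph.nodes, key=str)
    a = nx.to_numpy_array(graph, nodelist=nodes)
    c = np.linalg.solve(np.eye(n) - a.T / n, np.ones(n))
    c = np.sort(c)[::-1]
    return c / c.sum()


def schieber_d(
    graph_a: nx.Graph,
    graph_b: nx.Graph,
    weights: tuple[float, float, float] = (0.45, 0.45, 0.10),
) -> float:
    """Structural dissimilarity D in [0, 1] between two graphs.

    Edge weights are ignored: only hop-count structure matters. The two
    graphs may have different node sets and sizes.
    """
    for g in (graph_a, graph_b):
        if g.number_of_nodes() == 0:
            raise ValueError("schieber_d is undefined for an empty graph")
    w1, w2, w3 = weights

    prof_a, deff_a = _distance_profiles(graph_a)
    prof_b, deff_b = _distance_profiles(graph_b)
    mu_a, mu_b = _align(prof_a.mean(axis=0), prof_b.mean(axis=0))

    term1 = math.sqrt(max(_js_divergence(mu_a, mu_b), 0.0) / _LN2)
    term2 = abs(
        math.sqrt(_node_dispersion(prof_a, deff_a))
        - math.sqrt(_node_dispersion(prof_b, deff_b))
    )

    term3 = 0.0
    if w3 > 0:
        def centrality_half(ga: nx.Graph, gb: nx.Graph) -> float:
            ca = _alpha_centrality_dist(ga)
            cb = _alpha_centrality_dist(gb)
            width = max(len(ca), len(cb))
            pa = np.zeros(width)
            pb = np.zeros(width)
            pa[: len(ca)] = ca
            pb[: len(cb)] = cb
            return math.sqrt(max(_js_divergence(pa, pb), 0.0) / _LN2)

        term3 = 0.5 * (
            centrality_half(graph_a, graph_b)
            + centrality_half(nx.complement(graph_a), nx.complement(graph_b))
        )

    return w1 * term1 + w2 * term2 + w3 * term3


# ---------------------------------------------------------------------------
# multiple minimum spanning trees
# ---------------------------------------------------------------------------

@dataclass
class SkeletonRun:
    """Result of an iterated edge-disjoint MST extraction.

    ``trees[t]`` is the list of ``(u, v, weight)`` edges of iteration t;
    ``d_values[t]`` the dissimilarity between trees t and t+1.
    """

    nodes: list
    trees: list[list[tuple[Hashable, Hashable, float]]]
    d_values: list[float]
    stopped_early: bool = False
    depth: int | None = None

    def aggregate(self, m: int | None = None) -> nx.Graph:
        """Union of the first ``m`` trees (all trees when ``m`` is None)."""
        if m is None:
            m = len(self.trees)
        if not 1 <= m <= len(self.trees):
            raise ValueError(f"aggregation depth {m} outside 1..{len(self.trees)}")
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for tree in self.trees[:m]:
            g.add_weighted_edges_from(tree)
        self.depth = m
        return g

    def tree_graph(self, t: int) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.trees[t])
        return g


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def mmst(
    dm: DistanceMatrix,
    n_iter: int = 250,
    compute_d: bool = True,
) -> SkeletonRun:
    """Extract ``n_iter`` edge-disjoint minimum spanning trees.

    Iteration t takes the MST of the working graph (Kruskal; weight ties
    broken by the lexicographic edge key for determinism), records it, and
    removes its edges. If edge removal disconnects the working graph, the
    minimum spanning forest is recorded and the run stops early with a
    warning. Non-finite distances never enter the working graph.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n = len(dm.cells)
    if n < 2:
        raise ValueError("mmst requires at least 2 nodes")

    iu, ju = np.triu_indices(n, k=1)
    w = dm.matrix[iu, ju]
    finite = np.isfinite(w)
    iu, ju, w = iu[finite], ju[finite], w[finite]
    order = np.lexsort((ju, iu, w))
    iu, ju, w = iu[order], ju[order], w[order]
    alive = np.ones(len(w), dtype=bool)

    trees: list[list[tuple[Hashable, Hashable, float]]] = []
    stopped_early = False
    for t in range(n_iter):
        uf = _UnionFind(n)
        tree_idx: list[int] = []
        for e in np.flatnonzero(alive):
            if uf.union(int(iu[e]), int(ju[e])):
                tree_idx.append(int(e))
                if len(tree_idx) == n - 1:
                    break
        if not tree_idx:
            stopped_early = True
            break
        alive[tree_idx] = False
        trees.append(
            [(dm.cells[int(iu[e])], dm.cells[int(ju[e])], float(w[e])) for e in tree_idx]
        )
        if len(tree_idx) < n - 1:
            stopped_early = True
            logger.warning(
                "mmst: working graph disconnected at iteration %d; "
                "recorded a %d-edge spanning forest and stopped", t + 1, len(tree_idx)
            )
            break
    if stopped_early and len(trees) < n_iter:
        logger.warning("mmst: stopped after %d of %d iterations", len(trees), n_iter)

    run = SkeletonRun(nodes=list(dm.cells), trees=trees, d_values=[], stopped_early=stopped_early)
    if compute_d and len(trees) > 1:
        run.d_values = [
            schieber_d(run.tree_graph(t), run.tree_graph(t + 1))
            for t in range(len(trees) - 1)
        ]
    return run


def choose_depth(
    run: SkeletonRun,
    window: int = 10,
    flat_fraction: float = 0.25,
    override: int | None = None,
) -> int:
    """Aggregation depth from the D-value series.

    Returns the end index of the first length-``window`` window whose
    standard deviation falls to at most ``flat_fraction`` times the
    standard deviation of the initial window — i.e. where successive trees
    stop adding information. ``override`` short-circuits the rule (e.g. a
    fixed depth of 20).
    """
    if override is not None:
        if override < 1:
            raise ValueError("override depth must be >= 1")
        return override
    series = np.asarray(run.d_values, dtype=float)
    if len(series) < window:
        raise ValueError(f"D-value series of length {len(series)} shorter than window={window}")
    ref = float(np.std(series[:window]))
    threshold = flat_fraction * ref + 1e-12  # epsilon absorbs fp noise on flat series
    for t in range(window, len(series) + 1):
        if float(np.std(series[t - window:t])) <= threshold:
            return t
    return len(series)


def network_stats(graph: nx.Graph) -> dict:
    """Node/edge counts, density 2e/(n(n-1)), average degree 2e/n, and the
    hop-count diameter of the largest connected component."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("network_stats requires a nonempty graph")
    e = graph.number_of_edges()
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    largest = max(nx.connected_components(graph), key=len)
    diameter = nx.diameter(graph.subgraph(largest)) if len(largest) > 1 else 0
    return {
        "n_nodes": n,
        "n_edges": e,
        "density": density,
        "average_degree": 2 * e / n,
        "diameter": diameter,
    }


def skeleton_walk(
    graph: nx.Graph,
    partition,
    steps: int,
    start_community: int | None = None,
) -> list[dict]:
    """Walk the skeleton through high-degree nodes, reporting neighborhoods.

    Starts at the highest-degree node of ``start_community`` (default: the
    community of the globally highest-degree node); at each step reports
    the current node's open neighborhood with its community composition,
    then moves to the highest-degree unvisited neighbor. Ties break
    lexicographically by node id. Truncates with a warning when no fresh
    neighbor remains.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if steps == 0 or graph.number_of_nodes() == 0:
        return []
    labels = partition.labels
    by_degree = lambda nd: (-graph.degree(nd), str(nd))
    if start_community is None:
        start = min(graph.nodes, key=by_degree)
    else:
        members = [nd for nd in graph.nodes if labels.get(nd) == start_community]
        if not members:
            raise ValueError(f"community {start_community} has no nodes in the graph")
        start = min(members, key=by_degree)

    current = start
    visited = {current}
    out: list[dict] = []
    for _ in range(steps):
        nbrs = set(graph[current])
        out.append(
            {
                "node": current,
                "community": labels.get(current),
                "neighborhood": sorted(nbrs, key=str),
                "composition": dict(Counter(labels.get(nd) for nd in nbrs)),
            }
        )
        fresh = [nd for nd in nbrs if nd not in visited]
        if not fresh:
            warnings.warn("skeleton_walk: no unvisited neighbor; walk truncated")
            break
        current = min(fresh, key=by_degree)
        visited.add(current)
    return out


def write_skeleton(graph: nx.Graph, edgelist_path: str | Path, graphml_path: str | Path | None = None) -> None:
    with open(edgelist_path, "w", encoding="utf-8") as fh:
        fh.write("node1,node2,weight\n")
        for u, v, d in sorted(graph.edges(data=True), key=lambda t: (str(t[0]), str(t[1]))):
            fh.write(f"{u},{v},{d.get('weight', 1.0)}\n")
    if graphml_path is not None:
        out = nx.relabel_nodes(graph, {nd: str(nd) for nd in graph.nodes})
        nx.write_graphml(out, graphml_path)


def write_d_series(run: SkeletonRun, path: str | Path) -> None:
    pd.DataFrame(
        {"iteration": range(1, len(run.d_values) + 1), "d_value": run.d_values}
    ).to_csv(path, index=False)
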