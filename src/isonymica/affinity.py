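"""Paternal-maternal surname affinity network construction and filtering.

Nodes are surnames; an edge's weight ``n_ss`` counts the persons bearing
the unordered pair {s1, s2}, irrespective of slot order. An edge is kept
only when its weight is at least ``k`` times the count expected under
random pairing, ``k * n_s1 * n_s2 / N``; the surviving graph is then
reduced to its degree core.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "count_pairs",
    "affinity_filter",
    "k_core",
    "surname_ses",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
]


def count_pairs(records: pd.DataFrame) -> nx.Graph:
    """Build the weighted surname-pair graph from person records.

    Edge weight(s1, s2) = number of persons with surname pair {s1, s2}
    in either slot order. The node attribute ``n_s`` counts person-slots
    (a person bearing s in both slots contributes 2). Persons whose two
    surnames are identical produce no edge but are counted in ``n_s``.
    The graph attribute ``N`` is the total number of persons.
    """
    g = nx.Graph()
    g.graph["N"] = int(len(records))
    if records.empty:
        return g

    slot_counts: Counter = Counter(records["paternal_surname"])
    slot_counts.update(records["maternal_surname"])

    pair_counts: Counter = Counter()
    for s1, s2 in zip(records["paternal_surname"], records["maternal_surname"]):
        if s1 != s2:
            pair_counts[(s1, s2) if s1 <= s2 else (s2, s1)] += 1

    g.add_nodes_from((s, {"n_s": c}) for s, c in slot_counts.items())
    g.add_weighted_edges_from((a, b, w) for (a, b), w in pair_counts.items())

    if "ses" in records.columns:
        for s, m in surname_ses(records).items():
            g.nodes[s]["mean_ses"] = m
    return g


def affinity_filter(graph: nx.Graph, k: float = 100.0) -> nx.Graph:
    """Keep only edges whose weight meets the random-pairing threshold.

    Edge {s1, s2} is retained iff ``n_ss >= k * n_s1 * n_s2 / N``; nodes
    left isolated are removed. Monotone in ``k``: larger ``k`` retains a
    subset of the edges kept at smaller ``k``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k!r}")
    n_total = graph.graph.get("N")
    if not n_total:
        raise ValueError("graph lacks the total person count N")

    out = nx.Graph(**graph.graph)
    out.add_nodes_from(graph.nodes(data=True))
    for s1, s2, data in graph.edges(data=True):
        expected = graph.nodes[s1]["n_s"] * graph.nodes[s2]["n_s"] / n_total
        if data["weight"] >= k * expected:
            out.add_edge(s1, s2, **data)
    out.remove_nodes_from([n for n in out if out.degree(n) == 0])
    logger.info(
        "affinity_filter(k=%g): %d -> %d nodes, %d -> %d edges",
        k, graph.number_of_nodes(), out.number_of_nodes(),
        graph.number_of_edges(), out.number_of_edges(),
    )
    return out


def k_core(graph: nx.Graph, k_core_min: int = 3) -> nx.Graph:
    """Maximal subgraph in which every node has degree >= ``k_core_min``.

    Standard iterative peeling; the empty graph is a valid result.
    """
    if k_core_min < 1:
        raise ValueError(f"k_core_min must be >= 1, got {k_core_min!r}")
    core = nx.k_core(graph, k=k_core_min)
    out = nx.Graph(**graph.graph)
    out.add_nodes_from((n, graph.nodes[n]) for n in core.nodes)
    out.add_edges_from((u, v, d) for u, v, d in core.edges(data=True))
    return out


def surname_ses(records: pd.DataFrame) -> dict[str, float]:
    """Arithmetic mean SES over the persons bearing each surname in either slot.

    A person with the same surname in both slots counts once.
    """
    if "ses" not in records.columns:
        raise ValueError("records lack a 'ses' column; run assign_person_ses first")
    sums: Counter = Counter()
    counts: Counter = Counter()
    for s1, s2, v in zip(records["paternal_surname"], records["maternal_surname"], records["ses"]):
        sums[s1] += v
        counts[s1] += 1
        if s2 != s1:
            sums[s2] += v
            counts[s2] += 1
    return {s: sums[s] / counts[s] for s in counts}


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Three-column weighted edge list: surname1, surname2, weight."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("surname1,surname2,weight\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u},{v},{d.get('weight', 1)}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path)
    g = nx.Graph()
    g.add_weighted_edges_from(df.itertuples(index=False, name=None))
    return g


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)
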