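"""Modularity community detection with consensus, and cluster profiling."""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "detect_consensus",
    "cluster_ses",
    "top_degree_surnames",
    "salient_surnames",
    "cohort_representation",
]


@dataclass
class Partition:
    """Assignment of graph nodes to integer community labels.

    Attributes
    ----------
    labels
        Node -> community label.
    modularity
        Weighted modularity of ``labels`` on the graph that was clustered,
        or ``None`` when no graph is attached (e.g. planted ground truth).
    n_runs
        Number of optimization runs behind this partition.
    method
        Free-form tag describing how the partition was obtained.
    modularity_range
        (min, max) modularity across the runs, when applicable.
    """

    labels: dict[Hashable, int]
    modularity: float | None = None
    n_runs: int = 1
    method: str = "unspecified"
    modularity_range: tuple[float, float] | None = None

    def communities(self) -> dict[int, set]:
        groups: dict[int, set] = defaultdict(set)
        for node, c in self.labels.items():
            groups[c].add(node)
        return dict(groups)

    def sizes(self) -> dict[int, int]:
        return {c: len(members) for c, members in self.communities().items()}

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def write(self, path: str | Path, summary_path: str | Path | None = None) -> None:
        """Write ``node,community`` rows; optionally a JSON summary."""
        path = Path(path)
        df = pd.DataFrame(
            sorted((str(n), c) for n, c in self.labels.items()),
            columns=["node", "community"],
        )
        df.to_csv(path, index=False)
        if summary_path is not None:
            summary = {
                "modularity": self.modularity,
                "n_runs": self.n_runs,
                "method": self.method,
                "modularity_range": list(self.modularity_range)
                if self.modularity_range
                else None,
                "community_sizes": {str(c): s for c, s in sorted(self.sizes().items())},
            }
            Path(summary_path).write_text(json.dumps(summary, indent=2))


def _canonical(communities: Iterable[frozenset]) -> frozenset:
    """Label-permutation-invariant fingerprint of a partition."""
    return frozenset(frozenset(c) for c in communities)


def _relabel(communities: Sequence[set]) -> dict[Hashable, int]:
    """Deterministic integer labels: largest community first, ties by min node."""
    ordered = sorted(communities, key=lambda c: (-len(c), min(str(n) for n in c)))
    labels: dict[Hashable, int] = {}
    for i, comm in enumerate(ordered):
        for node in comm:
            labels[node] = i
    return labels


def detect_consensus(
    graph: nx.Graph,
    n_runs: int = 10,
    seed: int | None = None,
    weight: str = "weight",
) -> Partition:
    """Run modularity optimization ``n_runs`` times and keep the consensus.

    Each run uses a distinct sub-seed derived from ``seed``. Partitions are
    grouped by equivalence up to label permutation; the most frequent
    equivalence class wins, ties broken by highest modularity.

    A graph without edges yields the singleton partition at modularity 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot detect communities on an empty graph")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")

    if graph.number_of_edges() == 0:
        labels = {n: i for i, n in enumerate(sorted(graph.nodes, key=str))}
        return Partition(labels, modularity=0.0, n_runs=n_runs, method="singletons",
                         modularity_range=(0.0, 0.0))

    sub_seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    runs: list[tuple[frozenset, list[set], float]] = []
    for s in sub_seeds:
        comms = nx.community.louvain_communities(graph, weight=weight, seed=int(s))
        q = nx.community.modularity(graph, comms, weight=weight)
        runs.append((_canonical(comms), [set(c) for c in comms], q))

    counts = Counter(key for key, _, _ in runs)
    best_key = max(
        counts,
        key=lambda k: (counts[k], max(q for key, _, q in runs if key == k)),
    )
    chosen = max(
        (r for r in runs if r[0] == best_key), key=lambda r: r[2]
    )
    qs = [q for _, _, q in runs]
    labels = _relabel(chosen[1])
    part = Partition(
        labels,
        modularity=chosen[2],
        n_runs=n_runs,
        method="louvain-consensus",
        modularity_range=(min(qs), max(qs)),
    )
    logger.info(
        "consensus over %d runs: %d communities, modularity %.4f (range %.4f-%.4f)",
        n_runs, part.n_communities, part.modularity, min(qs), max(qs),
    )
    return part


def cluster_ses(
    partition: Partition,
    surname_ses: Mapping[Hashable, float],
    person_counts: Mapping[Hashable, int] | None = None,
) -> dict[int, float]:
    """Mean SES per community.

    By default the unweighted mean over member surnames' mean SES.
    Pass ``person_counts`` (surname -> bearer count) for the
    person-weighted variant.
    """
    out: dict[int, float] = {}
    for comm, members in partition.communities().items():
        scored = [s for s in members if s in surname_ses]
        if not scored:
            logger.warning("community %s has no SES-bearing surname; excluded", comm)
            continue
        if person_counts is None:
            out[comm] = float(np.mean([surname_ses[s] for s in scored]))
        else:
            w = np.array([person_counts.get(s, 0) for s in scored], dtype=float)
            v = np.array([surname_ses[s] for s in scored], dtype=float)
            out[comm] = float(np.average(v, weights=w)) if w.sum() else float(np.mean(v))
    return out


def top_degree_surnames(
    partition: Partition, graph: nx.Graph, top_n: int = 10
) -> dict[int, list]:
    """Per community, the ``top_n`` members by (unweighted) degree.

    Ties are broken lexicographically by node id. Communities smaller than
    ``top_n`` are returned in full.
    """
    out: dict[int, list] = {}
    for comm, members in partition.communities().items():
        in_graph = [n for n in members if n in graph]
        ranked = sorted(in_graph, key=lambda n: (-graph.degree(n), str(n)))
        out[comm] = ranked[:top_n]
    return out


def salient_surnames(
    cells,
    cell_partition: Partition,
    top_k: int = 500,
    top_n: int = 10,
) -> dict[int, list[str]]:
    """Per area-community, surnames frequent inside and rare outside.

    Member cells' surname counts are pooled per community. Candidates are
    the community's ``top_k`` surnames by pooled relative frequency; they
    are ranked by the ratio of the in-community relative frequency to the
    maximum out-community relative frequency, the denominator floored at
    one pooled pseudo-count so exclusive surnames get a large finite score.
    """
    comm_counts: dict[int, Counter] = {}
    comm_total: dict[int, float] = {}
    for comm, cells_in in cell_partition.communities().items():
        counts: Counter = Counter()
        for cid in cells_in:
            if cid in cells.counts:
                counts.update(cells.counts[cid])
        if not counts:
            logger.warning("area community %s has no cells with data; skipped", comm)
            continue
        comm_counts[comm] = counts
        comm_total[comm] = sum(counts.values())

    freqs = {
        comm: {s: c / comm_total[comm] for s, c in counts.items()}
        for comm, counts in comm_counts.items()
    }

    out: dict[int, list[str]] = {}
    for comm, f_in in freqs.items():
        others = [c for c in freqs if c != comm]
        out_total = sum(comm_total[c] for c in others)
        floor = 1.0 / out_total if out_total else 1.0
        candidates = sorted(f_in, key=lambda s: (-f_in[s], str(s)))[:top_k]
        scored = []
        for s in candidates:
            f_out = max((freqs[c].get(s, 0.0) for c in others), default=0.0)
            scored.append((s, f_in[s] / max(f_out, floor)))
        scored.sort(key=lambda t: (-t[1], str(t[0])))
        out[comm] = [s for s, _ in scored[:top_n]]
    return out


def cohort_representation(
    cohort: pd.DataFrame,
    partition: Partition,
    period_col: str = "period",
) -> pd.DataFrame:
    """Fraction of cohort members per period bearing each community's surnames.

    Every non-period column of ``cohort`` is treated as a surname slot; a
    member counts toward a community when at least one of their surnames is
    assigned to it, so a member may count toward several communities and
    per-period fractions may sum above 1.

    Returns a frame indexed by period with one column per community label.
    """
    if period_col not in cohort.columns:
        raise ValueError(f"cohort table lacks a '{period_col}' column")
    surname_cols = [c for c in cohort.columns if c != period_col]
    if not surname_cols:
        raise ValueError("cohort table has no surname columns")

    comms = sorted(set(partition.labels.values()))
    rows = {}
    for period, grp in cohort.groupby(period_col):
        n = len(grp)
        if n == 0:
            rows[period] = {c: np.nan for c in comms}
            continue
        hits = {c: 0 for c in comms}
        for _, rec in grp.iterrows():
            member_comms = {
                partition.labels[rec[col]]
                for col in surname_cols
                if pd.notna(rec[col]) and rec[col] in partition.labels
            }
            for c in member_comms:
                hits[c] += 1
        rows[period] = {c: hits[c] / n for c in comms}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
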