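import math

import networkx as nx
import numpy as np
import pytest

from isonymica.isonymy import DistanceMatrix
from isonymica.skeleton import (
    SkeletonRun,
    choose_depth,
    mmst,
    network_stats,
    schieber_d,
    skeleton_walk,
    write_d_series,
    write_skeleton,
)
from isonymica.communities import Partition


# ---------------------------------------------------------------------------
# independent brute-force oracle for the structural dissimilarity
# ---------------------------------------------------------------------------

def _oracle_profiles(g):
    """Node distance distributions via hand-rolled BFS (no scipy)."""
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    rows, fmax, unreachable = [], 0, False
    for s in nodes:
        dist = {s: 0}
        frontier, d = [s], 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in g[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        bins = [0.0] * n  # distances 1..n-1, then one unreachable bin
        for t in nodes:
            if t == s:
                continue
            if t in dist:
                bins[dist[t] - 1] += 1
                fmax = max(fmax, dist[t])
            else:
                bins[-1] += 1
                unreachable = True
        rows.append([b / (n - 1) for b in bins])
    return rows, fmax + (1 if unreachable else 0)


def _oracle_js(p, q):
    total = 0.0
    for a, b in zip(p, q):
        m = (a + b) / 2.0
        if a > 0:
            total += 0.5 * a * math.log(a / m)
        if b > 0:
            total += 0.5 * b * math.log(b / m)
    return total


def _oracle_nnd(rows, d_eff):
    if d_eff == 0:
        return 0.0
    n = len(rows)
    width = len(rows[0])
    mu = [sum(r[b] for r in rows) / n for b in range(width)]
    total = 0.0
    for r in rows:
        for b in range(width):
            if r[b] > 0:
                total += r[b] * math.log(r[b] / mu[b])
    return (total / n) / math.log(d_eff + 1)


def _oracle_alpha_centrality(g):
    """Bonacich alpha-centrality via Neumann series (independent of solve)."""
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    adj = [[0.0] * n for _ in range(n)]
    for u, v in g.edges:
        adj[idx[u]][idx[v]] = adj[idx[v]][idx[u]] = 1.0
    a = 1.0 / n
    c = [1.0] * n
    term = [1.0] * n
    for _ in range(5000):
        term = [a * sum(adj[i][j] * term[j] for j in range(n)) for i in range(n)]
        c = [ci + ti for ci, ti in zip(c, term)]
        if max(term) < 1e-17:
            break
    s = sum(c)
    return sorted((ci / s for ci in c), reverse=True)


def _pad(a, b):
    width = max(len(a), len(b))
    return a + [0.0] * (width - len(a)), b + [0.0] * (width - len(b))


def oracle_d(ga, gb, w=(0.45, 0.45, 0.10)):
    rows_a, deff_a = _oracle_profiles(ga)
    rows_b, deff_b = _oracle_profiles(gb)
    na, nb = len(rows_a), len(rows_b)
    mu_a = [sum(r[b] for r in rows_a) / na for b in range(len(rows_a[0]))]
    mu_b = [sum(r[b] for r in rows_b) / nb for b in range(len(rows_b[0]))]
    fa, fb = _pad(mu_a[:-1], mu_b[:-1])
    term1 = math.sqrt(max(_oracle_js(fa + [mu_a[-1]], fb + [mu_b[-1]]), 0.0) / math.log(2))
    term2 = abs(math.sqrt(_oracle_nnd(rows_a, deff_a)) - math.sqrt(_oracle_nnd(rows_b, deff_b)))

    def half(x, y):
        cx, cy = _pad(_oracle_alpha_centrality(x), _oracle_alpha_centrality(y))
        return math.sqrt(max(_oracle_js(cx, cy), 0.0) / math.log(2))

    term3 = 0.5 * (half(ga, gb) + half(nx.complement(ga), nx.complement(gb)))
    return w[0] * term1 + w[1] * term2 + w[2] * term3


SMALL_GRAPHS = [
    nx.path_graph(5),
    nx.star_graph(4),
    nx.cycle_graph(6),
    nx.complete_graph(4),
    nx.complete_graph(6),
    nx.Graph([(0, 1), (2, 3)]),  # disconnected
    nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("d", "e")]),
]
SMALL_GRAPHS += [nx.gnp_random_graph(n, p, seed=s)
                 for n in (4, 5, 6) for p, s in ((0.4, 1), (0.6, 2), (0.8, 3))]


class TestSchieberD:
    def test_self_dissimilarity_zero(self):
        for g in SMALL_GRAPHS:
            assert schieber_d(g, g) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        for i in range(0, len(SMALL_GRAPHS) - 1, 2):
            a, b = SMALL_GRAPHS[i], SMALL_GRAPHS[i + 1]
            assert schieber_d(a, b) == pytest.approx(schieber_d(b, a), abs=1e-12)

    def test_path_vs_star_positive(self):
        assert schieber_d(nx.path_graph(5), nx.star_graph(4)) > 0.0

    def test_bounded_unit_interval(self):
        for i, a in enumerate(SMALL_GRAPHS):
            for b in SMALL_GRAPHS[i + 1:]:
                assert 0.0 <= schieber_d(a, b) <= 1.0

    def test_agrees_with_brute_force_oracle(self):
        for i, a in enumerate(SMALL_GRAPHS):
            for b in SMALL_GRAPHS[i:]:
                assert schieber_d(a, b) == pytest.approx(oracle_d(a, b), abs=1e-9)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            schieber_d(nx.Graph(), nx.path_graph(3))


def random_dm(n, seed):
    rng = np.random.default_rng(seed)
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(cells=[(i, 0) for i in range(n)], matrix=m, metric="euclid")


class TestMMST:
    def test_first_tree_is_mst(self):
        dm = random_dm(8, seed=0)
        run = mmst(dm, n_iter=1, compute_d=False)
        g = nx.Graph()
        for i in range(8):
            for j in range(i + 1, 8):
                g.add_edge((i, 0), (j, 0), weight=dm.matrix[i, j])
        expected = nx.minimum_spanning_tree(g)
        assert sum(w for _, _, w in run.trees[0]) == pytest.approx(
            expected.size(weight="weight")
        )

    def test_trees_edge_disjoint(self):
        run = mmst(random_dm(10, seed=1), n_iter=4, compute_d=False)
        seen = set()
        for tree in run.trees:
            edges = {frozenset((u, v)) for u, v, _ in tree}
            assert not (edges & seen)
            seen |= edges

    def test_tree_sizes_and_conservation(self):
        n, m = 12, 5
        run = mmst(random_dm(n, seed=2), n_iter=m, compute_d=False)
        assert all(len(t) == n - 1 for t in run.trees)
        g = run.aggregate(m)
        assert g.number_of_edges() == sum(len(t) for t in run.trees[:m]) == m * (n - 1)

    def test_early_stop_on_exhaustion(self):
        # K4 has 6 edges = exactly two disjoint spanning trees
        run = mmst(random_dm(4, seed=3), n_iter=5, compute_d=False)
        assert len(run.trees) == 2
        assert run.stopped_early

    def test_deterministic_under_ties(self):
        m = np.ones((6, 6))
        np.fill_diagonal(m, 0.0)
        dm = DistanceMatrix(cells=[(i, 0) for i in range(6)], matrix=m, metric="euclid")
        a = mmst(dm, n_iter=3, compute_d=False)
        b = mmst(dm, n_iter=3, compute_d=False)
        assert a.trees == b.trees

    def test_d_values_recorded_between_consecutive_trees(self):
        run = mmst(random_dm(9, seed=4), n_iter=4)
        assert len(run.d_values) == len(run.trees) - 1
        assert all(0.0 <= d <= 1.0 for d in run.d_values)

    def test_d_values_match_direct_computation(self):
        run = mmst(random_dm(7, seed=5), n_iter=3)
        direct = schieber_d(run.tree_graph(0), run.tree_graph(1))
        assert run.d_values[0] == pytest.approx(direct, abs=1e-12)

    def test_aggregate_depth_validation(self):
        run = mmst(random_dm(6, seed=6), n_iter=2, compute_d=False)
        with pytest.raises(ValueError):
            run.aggregate(99)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            mmst(random_dm(4, seed=0), n_iter=0)


class TestChooseDepth:
    def make_run(self, d_values):
        return SkeletonRun(nodes=[], trees=[], d_values=list(d_values))

    def test_constant_series_returns_window(self):
        assert choose_depth(self.make_run([0.3] * 30), window=10) == 10

    def test_knee_series(self):
        series = [1.0, 0.8, 0.6, 0.4, 0.2] + [0.2] * 20
        got = choose_depth(self.make_run(series), window=5, flat_fraction=0.25)
        # brute-force scan with the documented rule
        ref = 0.25 * float(np.std(series[:5]))
        expected = next(
            t for t in range(5, len(series) + 1)
            if float(np.std(series[t - 5:t])) <= ref
        )
        assert got == expected
        assert all(abs(v - 0.2) < 1e-12 for v in series[got - 5:got])

    def test_override(self):
        assert choose_depth(self.make_run([0.5] * 3), window=10, override=20) == 20

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            choose_depth(self.make_run([0.1, 0.2]), window=10)


class TestNetworkStats:
    def test_complete_graph(self):
        s = network_stats(nx.complete_graph(5))
        assert s["density"] == pytest.approx(1.0)
        assert s["diameter"] == 1

    def test_path_graph(self):
        s = network_stats(nx.path_graph(5))
        assert s["density"] == pytest.approx(0.4)
        assert s["diameter"] == 4
        assert s["average_degree"] == pytest.approx(1.6)

    def test_disconnected_uses_largest_component(self):
        g = nx.Graph([(0, 1), (1, 2), (3, 4)])
        assert network_stats(g)["diameter"] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            network_stats(nx.Graph())


class TestSkeletonWalk:
    def test_star_hub_sees_all_leaves(self):
        g = nx.star_graph(6)
        part = Partition({n: 0 for n in g.nodes})
        steps = skeleton_walk(g, part, steps=1)
        assert steps[0]["node"] == 0
        assert set(steps[0]["neighborhood"]) == set(range(1, 7))

    def test_zero_steps(self):
        g = nx.star_graph(3)
        assert skeleton_walk(g, Partition({n: 0 for n in g.nodes}), steps=0) == []

    def test_two_cliques_cross_late(self):
        # K6 on a0..a5, triangle on b0..b2, bridge node b0 tied to a0..a3.
        # Degrees: a0..a3 = 6, b0 = 6, a4/a5 = 5, so lexicographic
        # tie-breaking walks a0 -> a1 -> a2 -> a3 before b0 wins at step 5.
        g = nx.complete_graph([f"a{i}" for i in range(6)])
        g.add_edges_from([("b0", "b1"), ("b0", "b2"), ("b1", "b2")])
        g.add_edges_from([("b0", f"a{i}") for i in range(4)])
        labels = {n: (0 if n.startswith("a") else 1) for n in g.nodes}
        part = Partition(labels)
        walk = skeleton_walk(g, part, steps=6, start_community=0)
        communities_seen = [labels[s["node"]] for s in walk]
        assert communities_seen[:5] == [0, 0, 0, 0, 1]
        assert [s["node"] for s in walk[:5]] == ["a0", "a1", "a2", "a3", "b0"]

    def test_truncation_warns(self):
        g = nx.path_graph(3)
        part = Partition({n: 0 for n in g.nodes})
        with pytest.warns(UserWarning, match="truncated"):
            walk = skeleton_walk(g, part, steps=10)
        assert len(walk) < 10


class TestWriters:
    def test_skeleton_and_d_series_files(self, tmp_path):
        run = mmst(random_dm(6, seed=8), n_iter=3)
        g = run.aggregate(2)
        write_skeleton(g, tmp_path / "sk.csv", tmp_path / "sk.graphml")
        write_d_series(run, tmp_path / "d.csv")
        assert (tmp_path / "sk.csv").read_text().startswith("node1,node2,weight")
        assert (tmp_path / "d.csv").exists()
        assert (tmp_path / "sk.graphml").exists()
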