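"""Coexpression-network construction tests: adjacency, topological overlap
(against a naive O(n^3) oracle), dendrogram, dynamic tree cut contract,
eigengene merging, connectivity and betweenness (against a path-counting
oracle)."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ascnet import (
    ExpressionMatrix,
    ModulePartition,
    adjacency,
    betweenness,
    cluster_dendrogram,
    dynamic_tree_cut,
    intramodular_connectivity,
    merge_modules,
    module_eigengene,
    tom,
    tom_dissimilarity,
    top_edges,
)
from conftest import make_matrix


def _frame(m, prefix="p"):
    idx = [f"{prefix}{i:03d}" for i in range(m.shape[0])]
    return pd.DataFrame(m, index=idx, columns=idx)


def random_adjacency(n, rng):
    m = rng.uniform(0, 1, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return _frame(m)


def tom_oracle(a: pd.DataFrame) -> np.ndarray:
    """Naive triple-loop topological overlap."""
    m = a.to_numpy().copy()
    np.fill_diagonal(m, 0.0)
    n = len(m)
    out = np.eye(n)
    k = m.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(m[i, u] * m[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (l + m[i, j]) / (min(k[i], k[j]) + 1 - m[i, j])
    return out


def betweenness_oracle(edges: pd.DataFrame) -> dict:
    """Exhaustive BFS path-counting betweenness for small graphs."""
    import collections

    adj = collections.defaultdict(set)
    for s, t in edges[["source", "target"]].itertuples(index=False):
        adj[s].add(t)
        adj[t].add(s)
    nodes = sorted(adj)
    score = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        # BFS from s: shortest distance and path counts
        dist, paths = {s: 0}, {s: 1.0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        paths[v] = 0.0
                        nxt.append(v)
                    if dist[v] == dist[u] + 1:
                        paths[v] += paths[u]
            frontier = nxt
        if t not in dist:
            continue
        # count paths through each interior node w: paths(s->w)*paths(w->t)
        dist_t, paths_t = {t: 0}, {t: 1.0}
        frontier = [t]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist_t:
                        dist_t[v] = dist_t[u] + 1
                        paths_t[v] = 0.0
                        nxt.append(v)
                    if dist_t[v] == dist_t[u] + 1:
                        paths_t[v] += paths_t[u]
            frontier = nxt
        for w in nodes:
            if w in (s, t) or w not in dist or w not in dist_t:
                continue
            if dist[w] + dist_t[w] == dist[t]:
                score[w] += paths[w] * paths_t[w] / paths[t]
    return score


class TestAdjacency:
    def test_powers_of_known_correlations(self):
        t = np.linspace(0, 1, 8)
        rows = np.stack([t, -t, 2 * t + 5])
        x = make_matrix(rows, ["none"], list(range(8)), ["1"])
        a = adjacency(x, power=8)
        assert a.iloc[0, 1] == pytest.approx(1.0)  # r = -1, unsigned
        assert a.iloc[0, 2] == pytest.approx(1.0)  # affine rescaling invariant
        a1 = adjacency(x, power=1)
        assert np.allclose(a1.to_numpy(), a.to_numpy())  # |r| in {0,1} here

    def test_half_correlation_to_the_eighth(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=2000)
        e = rng.normal(size=2000)
        rows = np.stack([z, 0.5 * z + np.sqrt(0.75) * e])
        x = make_matrix(rows, ["none"], list(range(2000)), ["1"])
        a = adjacency(x, power=8)
        r = np.corrcoef(rows)[0, 1]
        assert a.iloc[0, 1] == pytest.approx(abs(r) ** 8)
        assert 0.001 < a.iloc[0, 1] < 0.02  # near 0.5^8

    def test_constant_probe_gets_zero_and_few_samples_rejected(self):
        rows = np.array([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        x = make_matrix(rows, ["none"], list(range(4)), ["1"])
        a = adjacency(x)
        assert a.iloc[0, 1] == 0.0
        with pytest.raises(ValueError, match="3 samples"):
            adjacency(make_matrix(rows[:, :2], ["none"], [0, 1], ["1"]))


class TestTOM:
    def test_all_ones_adjacency_gives_tom_one(self):
        a = _frame(np.ones((3, 3)) - np.eye(3))
        t = tom(a)
        assert np.allclose(t.to_numpy(), 1.0)

    def test_zero_adjacency_gives_identity(self):
        t = tom(_frame(np.zeros((4, 4))))
        assert np.allclose(t.to_numpy(), np.eye(4))

    def test_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            a = random_adjacency(50, rng)
            assert np.abs(tom(a).to_numpy() - tom_oracle(a)).max() < 1e-12

    def test_range_symmetry_and_asymmetric_input_rejected(self):
        rng = np.random.default_rng(1)
        a = random_adjacency(30, rng)
        t = tom(a).to_numpy()
        assert t.min() >= 0 and t.max() <= 1
        assert np.allclose(t, t.T)
        bad = a.copy()
        bad.iloc[0, 1] += 1e-3
        with pytest.raises(ValueError, match="symmetric"):
            tom(bad)


class TestDendrogram:
    def test_two_separated_blocks_are_top_branches(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        z = cluster_dendrogram(_frame(d))
        # the last merge joins two clusters of size 3 at height 1
        assert z[-1, 3] == 6 and z[-1, 2] == pytest.approx(1.0)
        assert z[-2, 3] == 3

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(0)
        d = random_adjacency(40, rng)  # symmetric, zero diagonal
        z = cluster_dendrogram(d)
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    def test_permutation_invariance_up_to_relabelling(self):
        rng = np.random.default_rng(3)
        d = random_adjacency(25, rng)
        perm = rng.permutation(25)
        dp = d.iloc[perm, perm]
        part1 = dynamic_tree_cut(cluster_dendrogram(d), d, min_size=5)
        part2 = dynamic_tree_cut(cluster_dendrogram(dp), dp, min_size=5)
        merged = pd.concat(
            [part1.labels.rename("a"), part2.labels.rename("b")], axis=1
        )
        grouped = merged.groupby("a")["b"].nunique()
        assert (grouped == 1).all()

    def test_nan_rejected(self):
        d = _frame(np.zeros((4, 4)))
        d.iloc[0, 1] = d.iloc[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            cluster_dendrogram(d)


def _block_diss(sizes, within, between, rng):
    n = sum(sizes)
    d = rng.uniform(between - 0.05, min(between + 0.05, 1.0), (n, n))
    start = 0
    for s in sizes:
        d[start : start + s, start : start + s] = rng.uniform(
            max(within - 0.05, 0.0), within + 0.05, (s, s)
        )
        start += s
    d = np.triu(d, 1)
    d = d + d.T
    return _frame(d)


class TestDynamicTreeCut:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        d = _block_diss([50, 50], 0.1, 0.95, rng)
        part = dynamic_tree_cut(cluster_dendrogram(d), d)
        assert len(part.module_names) == 2
        labels = part.labels.to_numpy()
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        assert labels[0] != labels[50]

    def test_min_size_dissolves_small_tight_cluster(self):
        rng = np.random.default_rng(1)
        d = _block_diss([5, 60], 0.05, 0.95, rng)
        part = dynamic_tree_cut(cluster_dendrogram(d), d, min_size=8)
        assert (part.labels.iloc[:5] == "grey").all()

    def test_all_noise_mostly_grey(self):
        rng = np.random.default_rng(2)
        x = make_matrix(
            rng.normal(8, 0.5, (200, 24)), ["none"], list(range(24)), ["1"]
        )
        d = tom_dissimilarity(tom(adjacency(x)))
        part = dynamic_tree_cut(cluster_dendrogram(d), d)
        assert part.grey_fraction > 0.5

    def test_labels_stable_for_fixed_input(self):
        rng = np.random.default_rng(3)
        d = _block_diss([30, 20], 0.1, 0.9, rng)
        p1 = dynamic_tree_cut(cluster_dendrogram(d), d)
        p2 = dynamic_tree_cut(cluster_dendrogram(d), d)
        pd.testing.assert_series_equal(p1.labels, p2.labels)


class TestEigengene:
    def _module_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        profile = np.sin(np.linspace(0, 3, 12))
        rows = profile[None, :] * rng.uniform(1, 3, 10)[:, None] + rng.normal(
            0, 0.05, (10, 12)
        )
        x = make_matrix(rows, ["none"], list(range(12)), ["1"])
        part = ModulePartition(pd.Series("blue", index=x.probes))
        return x, part, profile

    def test_identical_profiles_recovered_up_to_scale(self):
        x, part, profile = self._module_matrix()
        eig = module_eigengene(x, part)["blue"].to_numpy()
        c = np.corrcoef(eig, profile)[0, 1]
        assert c > 0.999

    def test_sign_oriented_to_module_mean(self):
        x, part, _ = self._module_matrix()
        eig = module_eigengene(x, part)["blue"].to_numpy()
        mean = x.values.mean(axis=0).to_numpy()
        assert np.corrcoef(eig, mean)[0, 1] >= 0

    def test_pc1_explains_at_least_any_single_probe(self):
        x, part, _ = self._module_matrix(seed=5)
        eig = module_eigengene(x, part)["blue"].to_numpy()
        v = x.values.to_numpy()
        z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)
        var_eig = (z @ eig) @ (z @ eig)
        for row in z:
            u = row / np.linalg.norm(row)
            assert var_eig >= (z @ u) @ (z @ u) - 1e-9


class TestMergeModules:
    def _two_module_data(self, corr_target, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=24)
        other = corr_target * base + np.sqrt(1 - corr_target**2) * rng.normal(size=24)
        rows = np.concatenate(
            [
                base[None, :] + rng.normal(0, 0.05, (20, 24)),
                other[None, :] + rng.normal(0, 0.05, (20, 24)),
            ]
        )
        x = make_matrix(rows, ["none"], list(range(24)), ["1"])
        labels = pd.Series(["blue"] * 20 + ["red"] * 20, index=x.probes)
        return x, ModulePartition(labels)

    def test_highly_correlated_eigengenes_merged(self):
        x, part = self._two_module_data(0.95)
        merged = merge_modules(x, part, merge_cut=0.2)
        assert len(merged.module_names) == 1

    def test_weakly_correlated_eigengenes_kept(self):
        x, part = self._two_module_data(0.5)
        merged = merge_modules(x, part, merge_cut=0.2)
        assert len(merged.module_names) == 2

    def test_merging_never_increases_count_and_preserves_grey(self):
        x, part = self._two_module_data(0.95)
        part.labels.iloc[:3] = "grey"
        part = ModulePartition(part.labels)
        merged = merge_modules(x, part)
        assert len(merged.module_names) <= len(part.module_names)
        assert (merged.labels.iloc[:3] == "grey").all()


class TestIntramodularConnectivity:
    def test_singleton_and_full_clique(self):
        a = _frame(np.ones((4, 4)) - np.eye(4))
        labels = pd.Series(["blue", "blue", "blue", "red"], index=a.index)
        kw = intramodular_connectivity(a, ModulePartition(labels))
        assert np.allclose(kw.iloc[:3], 2.0)
        assert kw.iloc[3] == 0.0

    def test_matches_masked_row_sum_on_random_instances(self):
        rng = np.random.default_rng(7)
        a = random_adjacency(30, rng)
        labels = pd.Series(
            rng.choice(["blue", "red", "grey"], 30), index=a.index
        )
        kw = intramodular_connectivity(a, ModulePartition(labels))
        for i, probe in enumerate(a.index):
            lab = labels.iloc[i]
            expected = 0.0
            if lab != "grey":
                expected = sum(
                    a.iloc[i, j]
                    for j in range(30)
                    if j != i and labels.iloc[j] == lab
                )
            assert kw.loc[probe] == pytest.approx(expected)


class TestTopEdges:
    def test_budget_selects_largest_and_sorts_descending(self):
        rng = np.random.default_rng(0)
        t = random_adjacency(4, rng)
        edges = top_edges(t, budget=3)
        assert len(edges) == 3
        assert (np.diff(edges["weight"]) <= 0).all()
        all_w = np.sort(t.to_numpy()[np.triu_indices(4, 1)])[::-1]
        assert np.allclose(edges["weight"], all_w[:3])

    def test_budget_beyond_pairs_returns_all(self):
        rng = np.random.default_rng(1)
        edges = top_edges(random_adjacency(5, rng), budget=1000)
        assert len(edges) == 10
        assert (edges["source"] < edges["target"]).all()


class TestBetweenness:
    def _edges(self, pairs):
        return pd.DataFrame(pairs, columns=["source", "target"])

    def test_path_graph(self):
        b = betweenness(self._edges([("A", "B"), ("B", "C")]))
        assert b["B"] == pytest.approx(1.0)
        assert b["A"] == b["C"] == 0.0

    def test_complete_graph_zero(self):
        b = betweenness(self._edges([("A", "B"), ("B", "C"), ("A", "C")]))
        assert np.allclose(b.to_numpy(), 0.0)

    def test_star_center(self):
        b = betweenness(
            self._edges([("hub", leaf) for leaf in "ABCD"])
        )
        assert b["hub"] == pytest.approx(6.0)  # C(4,2)

    def test_matches_path_counting_oracle_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(5, 25))
            pairs = [
                (f"n{i}", f"n{j}")
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.25
            ]
            if not pairs:
                continue
            edges = self._edges(pairs)
            mine = betweenness(edges)
            oracle = betweenness_oracle(edges)
            for node, val in oracle.items():
                assert mine[node] == pytest.approx(val, abs=1e-9)
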