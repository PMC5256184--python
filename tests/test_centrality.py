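from collections import deque

import numpy as np
import pytest

from hubcentral.centrality import (
    Partition,
    best_partition,
    betweenness,
    degree,
    group_network_modules,
    participation_coefficient,
    profile_subject,
    within_module_degree,
)
from hubcentral.graphs import ConnectivityMatrix, DensityGrid, threshold_by_density
from tests.conftest import random_binary_graph


# ---------------------------------------------------------------------------
# Slow definitional oracles, independent of the implementations under test.

def bfs_counts(adj, source):
    """Distances and shortest-path counts from one source (BFS)."""
    n = len(adj)
    dist = np.full(n, -1)
    sigma = np.zeros(n)
    dist[source], sigma[source] = 0, 1
    q = deque([source])
    while q:
        u = q.popleft()
        for v in np.flatnonzero(adj[u]):
            if dist[v] == -1:
                dist[v] = dist[u] + 1
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def betweenness_oracle(adj):
    """B_i = sum over ordered pairs (h, j), h != j != i, of the fraction of
    shortest h-j paths through i; via pairwise path counting."""
    n = len(adj)
    dist = np.empty((n, n))
    sigma = np.empty((n, n))
    for s in range(n):
        dist[s], sigma[s] = bfs_counts(adj, s)
    b = np.zeros(n)
    for h in range(n):
        for j in range(n):
            if h == j or dist[h, j] < 0:
                continue
            for i in range(n):
                if i in (h, j):
                    continue
                # paths h->j through i exist iff d(h,i)+d(i,j)=d(h,j)
                if dist[h, i] >= 0 and dist[i, j] >= 0 and \
                        dist[h, i] + dist[i, j] == dist[h, j]:
                    b[i] += sigma[h, i] * sigma[i, j] / sigma[h, j]
    return b


def z_oracle(adj, labels):
    n = len(adj)
    z = np.zeros(n)
    for i in range(n):
        members = [j for j in range(n) if labels[j] == labels[i]]
        kin = [sum(adj[j, k] for k in members) for j in members]
        mu = np.mean(kin)
        sd = np.sqrt(np.mean((np.array(kin) - mu) ** 2))
        ki = sum(adj[i, k] for k in members)
        z[i] = (ki - mu) / sd if sd > 0 else 0.0
    return z


def p_oracle(adj, labels):
    n = len(adj)
    p = np.zeros(n)
    for i in range(n):
        k = adj[i].sum()
        if k == 0:
            continue
        s = 0.0
        for m in set(labels):
            kim = sum(adj[i, j] for j in range(n) if labels[j] == m)
            s += (kim / k) ** 2
        p[i] = 1.0 - s
    return p


def newman_q(adj, labels):
    """Newman modularity from its definition: Q = sum over edges within
    modules of (a_ij - k_i k_j / 2m) / 2m."""
    a = np.asarray(adj, dtype=float)
    k = a.sum(axis=1)
    two_m = a.sum()
    same = np.equal.outer(labels, labels)
    return float(((a - np.outer(k, k) / two_m) * same).sum() / two_m)


# ---------------------------------------------------------------------------

class TestDegree:
    def test_star_graph(self):
        a = np.zeros((5, 5), dtype=np.uint8)
        a[0, 1:] = 1
        a[1:, 0] = 1
        np.testing.assert_array_equal(degree(a), [4, 1, 1, 1, 1])

    def test_empty_graph(self):
        assert np.all(degree(np.zeros((6, 6), dtype=np.uint8)) == 0)

    def test_handshake_identity(self, rng):
        a = random_binary_graph(rng, 10, 0.4)
        assert degree(a).sum() == a.sum()  # = 2 |E|

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            degree(np.full((3, 3), 2) - 2 * np.eye(3, dtype=int))


class TestBetweenness:
    def test_path_graph_midpoint(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)
        np.testing.assert_allclose(betweenness(a), [0.0, 2.0, 0.0])

    def test_complete_graph_all_zero(self):
        a = np.ones((5, 5), dtype=np.uint8) - np.eye(5, dtype=np.uint8)
        assert np.all(betweenness(a) == 0)

    @pytest.mark.parametrize("n,p", [(4, 0.3), (5, 0.5), (6, 0.4), (7, 0.6)])
    def test_matches_path_counting_oracle(self, rng, n, p):
        for _ in range(25):
            a = random_binary_graph(rng, n, p)
            np.testing.assert_allclose(betweenness(a), betweenness_oracle(a),
                                       atol=1e-10)

    def test_disconnected_pairs_contribute_nothing(self):
        # two disjoint path graphs
        a = np.zeros((6, 6), dtype=np.uint8)
        for i, j in [(0, 1), (1, 2), (3, 4), (4, 5)]:
            a[i, j] = a[j, i] = 1
        np.testing.assert_allclose(betweenness(a), [0, 2, 0, 0, 2, 0])

    def test_normalized_divides_by_ordered_pairs(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)
        np.testing.assert_allclose(betweenness(a, normalized=True),
                                   [0.0, 1.0, 0.0])


class TestBestPartition:
    @staticmethod
    def two_cliques(bridge=True):
        a = np.zeros((10, 10), dtype=np.uint8)
        for block in (range(5), range(5, 10)):
            for i in block:
                for j in block:
                    if i != j:
                        a[i, j] = 1
        if bridge:
            a[0, 5] = a[5, 0] = 1
        return a

    def test_recovers_two_cliques_and_q_matches_definition(self):
        a = self.two_cliques()
        part = best_partition(a, n_restarts=10, seed=1)
        assert part.n_modules == 2
        assert len(set(part.labels[:5])) == 1
        assert len(set(part.labels[5:])) == 1
        assert part.labels[0] != part.labels[5]
        assert part.q == pytest.approx(newman_q(a, part.labels), abs=1e-12)

    def test_complete_graph_single_module(self):
        a = np.ones((6, 6), dtype=np.uint8) - np.eye(6, dtype=np.uint8)
        part = best_partition(a, n_restarts=10, seed=0)
        # any split of a complete graph has Q <= 0
        assert part.q <= 1e-12

    def test_edgeless_graph_single_module_q_zero(self):
        with pytest.warns(UserWarning, match="edgeless"):
            part = best_partition(np.zeros((5, 5), dtype=np.uint8))
        assert part.n_modules == 1 and part.q == 0.0

    def test_deterministic_given_seed(self, rng):
        a = random_binary_graph(rng, 15, 0.3)
        p1 = best_partition(a, n_restarts=5, seed=33)
        p2 = best_partition(a, n_restarts=5, seed=33)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        assert p1.q == p2.q

    def test_q_never_decreases_with_more_restarts(self, rng):
        a = random_binary_graph(rng, 20, 0.15)
        qs = [best_partition(a, n_restarts=k, seed=5).q for k in (1, 3, 10, 25)]
        assert np.all(np.diff(qs) >= -1e-15)


class TestWithinModuleDegree:
    def test_hand_example(self):
        # 4-node module, star inside: intra-degrees {3, 1, 1, 1}
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, 1:] = 1
        a[1:, 0] = 1
        part = Partition(np.ones(4, dtype=int), 0.0, 1, 0)
        z = within_module_degree(a, part)
        assert z[0] == pytest.approx((3 - 1.5) / np.sqrt(0.75), abs=1e-9)
        assert z[0] == pytest.approx(1.732, abs=1e-3)

    def test_equal_intra_degrees_all_zero(self):
        a = np.ones((4, 4), dtype=np.uint8) - np.eye(4, dtype=np.uint8)
        part = Partition(np.ones(4, dtype=int), 0.0, 1, 0)
        assert np.all(within_module_degree(a, part) == 0)

    def test_singleton_module_zero(self):
        a = np.zeros((3, 3), dtype=np.uint8)
        a[0, 1] = a[1, 0] = 1
        part = Partition(np.array([1, 1, 2]), 0.0, 1, 0)
        assert within_module_degree(a, part)[2] == 0.0


class TestParticipationCoefficient:
    def test_provincial_node_zero(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, 1] = a[1, 0] = 1
        part = Partition(np.array([1, 1, 2, 2]), 0.0, 1, 0)
        assert participation_coefficient(a, part)[0] == 0.0

    def test_even_split_gives_half(self):
        # node 0: 4 links, 2 in its own module, 2 in the other
        a = np.zeros((5, 5), dtype=np.uint8)
        for j in (1, 2, 3, 4):
            a[0, j] = a[j, 0] = 1
        part = Partition(np.array([1, 1, 1, 2, 2]), 0.0, 1, 0)
        assert participation_coefficient(a, part)[0] == pytest.approx(0.5)

    def test_isolated_node_zero(self):
        a = np.zeros((3, 3), dtype=np.uint8)
        part = Partition(np.array([1, 1, 2]), 0.0, 1, 0)
        assert participation_coefficient(a, part)[2] == 0.0

    def test_invariant_under_module_relabeling(self, rng):
        a = random_binary_graph(rng, 12, 0.4)
        labels = rng.integers(1, 4, size=12)
        part = Partition(labels, 0.0, 1, 0)
        perm = {1: 3, 2: 1, 3: 2}
        relabeled = Partition(np.array([perm[x] for x in labels]), 0.0, 1, 0)
        np.testing.assert_allclose(
            participation_coefficient(a, part),
            participation_coefficient(a, relabeled),
        )


class TestProfileSubject:
    @staticmethod
    def make_stack(rng, n=14):
        r = rng.uniform(-1, 1, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0.0)
        cm = ConnectivityMatrix("s", [f"n{i}" for i in range(n)], r)
        return threshold_by_density(cm)

    def test_default_grid_gives_31_values_per_node_per_metric(self, rng):
        stack = self.make_stack(rng)
        prof = profile_subject(stack, n_restarts=2, seed=0)
        counts = prof.values.groupby(["node", "metric"]).size()
        assert (counts == 31).all()
        assert set(prof.modularity) == set(stack.densities)

    def test_metrics_depend_only_on_that_densitys_graph(self, rng):
        stack = self.make_stack(rng, n=10)
        prof = profile_subject(stack, n_restarts=2, seed=0)
        d = stack.densities[5]
        k = prof.metric_matrix("degree")[d].to_numpy()
        np.testing.assert_array_equal(k, degree(stack[d]))

    def test_node_permutation_equivariance(self, rng):
        n = 10
        r = rng.uniform(-1, 1, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0.0)
        labels = [f"n{i}" for i in range(n)]
        perm = rng.permutation(n)
        cm1 = ConnectivityMatrix("s", labels, r)
        cm2 = ConnectivityMatrix(
            "s", [labels[i] for i in perm], r[np.ix_(perm, perm)]
        )
        p1 = profile_subject(threshold_by_density(cm1), n_restarts=4, seed=3)
        p2 = profile_subject(threshold_by_density(cm2), n_restarts=4, seed=3)
        a1 = p1.density_averaged()["degree"]
        a2 = p2.density_averaged()["degree"]
        for lab in labels:
            assert a1[lab] == pytest.approx(a2[lab], abs=1e-12)


class TestGroupNetworkModules:
    @staticmethod
    def modular_cm(rng, sid, hub_cross=0.0):
        n = 12
        labels = [f"n{i}" for i in range(n)]
        block = np.repeat([0, 1, 2], 4)
        r = np.where(np.equal.outer(block, block), 0.8, 0.05)
        r = r + rng.normal(0, 0.01, size=(n, n))
        r = (r + r.T) / 2
        if hub_cross:
            r[0, block != 0] += hub_cross
            r[block != 0, 0] += hub_cross
        np.fill_diagonal(r, 0.0)
        return ConnectivityMatrix(sid, labels, np.clip(r, -1, 1))

    def test_provincial_query_node_has_empty_intermodular_list(self, rng):
        mats = [self.modular_cm(rng, f"s{i}") for i in range(3)]
        summ = group_network_modules(mats, density=0.2, query_nodes=["n1"],
                                     n_restarts=5, seed=0)
        assert summ.neighbors["n1"]["other_module"] == []
        assert len(summ.neighbors["n1"]["same_module"]) > 0

    def test_boosted_hub_gains_intermodular_links(self, rng):
        base = [self.modular_cm(rng, f"h{i}") for i in range(3)]
        boosted = [self.modular_cm(rng, f"t{i}", hub_cross=0.6)
                   for i in range(3)]
        s_base = group_network_modules(base, density=0.3, query_nodes=["n0"],
                                       n_restarts=5, seed=1)
        s_boost = group_network_modules(boosted, density=0.3,
                                        query_nodes=["n0"], n_restarts=5,
                                        seed=1)
        assert s_boost.n_intermodular("n0") > s_base.n_intermodular("n0")

    def test_requires_two_matrices(self, rng):
        with pytest.raises(ValueError):
            group_network_modules([self.modular_cm(rng, "s0")])
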