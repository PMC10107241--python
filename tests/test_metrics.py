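"""Connectivity and cohesion metrics against brute-force oracles."""

import networkx as nx
import numpy as np
import pytest
from conftest import (clustering_oracle, max_modularity_oracle,
                      modularity_oracle, net_from_weights,
                      random_flock_matrix, set_partitions)

import flocknet as fn


def complete_net(n: int, weight: float = 1.0):
    w = np.full((n, n), weight, dtype=float)
    np.fill_diagonal(w, 0.0)
    return net_from_weights(w)


def star_net(n_leaves: int):
    w = np.zeros((n_leaves + 1, n_leaves + 1))
    w[0, 1:] = w[1:, 0] = 1.0
    return net_from_weights(w)


def test_normalized_average_degree_examples():
    assert fn.normalized_average_degree(complete_net(4)) == 1.0
    assert fn.normalized_average_degree(star_net(3)) == pytest.approx(0.5)
    assert fn.normalized_average_degree(net_from_weights(np.zeros((3, 3)))) == 0.0


def test_connectance_examples():
    assert fn.connectance(complete_net(5)) == 1.0
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.3
    w[1, 2] = w[2, 1] = 0.2
    assert fn.connectance(net_from_weights(w)) == pytest.approx(2 / 3)
    assert fn.connectance(net_from_weights(np.zeros((4, 4)))) == 0.0


def test_degree_connectance_identity_on_random_networks():
    """mean(deg)/(n-1) and 2L/(n(n-1)) are the same number, always."""
    rng = np.random.default_rng(3)
    for _ in range(200):
        n = int(rng.integers(3, 12))
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(0, 1, len(iu[0])) * (rng.random(len(iu[0])) < 0.6)
        w[iu] = vals
        w = w + w.T
        net = net_from_weights(w)
        assert fn.normalized_average_degree(net) == pytest.approx(
            fn.connectance(net), abs=1e-12)


def test_modularity_single_community_is_zero(two_triangles):
    part = fn.Partition(two_triangles.species_ids, (0,) * 6)
    assert fn.modularity_q(two_triangles, part) == pytest.approx(0.0)


def test_modularity_two_triangles_true_partition(two_triangles):
    part = fn.Partition(two_triangles.species_ids, (0, 0, 0, 1, 1, 1))
    assert fn.modularity_q(two_triangles, part) == pytest.approx(0.5)
    # exhaustive check: 0.5 is also the maximum over all partitions
    assert max_modularity_oracle(two_triangles.weights) == pytest.approx(0.5)


def test_modularity_singletons_negative(two_triangles):
    part = fn.Partition(two_triangles.species_ids, tuple(range(6)))
    # every community has w_c = 0, so Q = -sum (s_c/2W)^2 = -6 * (2/12)^2
    assert fn.modularity_q(two_triangles, part) == pytest.approx(-6 * (2 / 12) ** 2)


def test_modularity_matches_networkx_and_rescaling_invariance():
    """Q agrees with networkx's weighted modularity; uniform rescaling is a no-op."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(4, 9))
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        w[iu] = rng.uniform(0, 1, len(iu[0])) * (rng.random(len(iu[0])) < 0.7)
        w = w + w.T
        if w.sum() == 0:
            continue
        net = net_from_weights(w)
        labels = tuple(int(x) for x in rng.integers(0, 3, n))
        labels = tuple(np.unique(labels, return_inverse=True)[1])
        part = fn.Partition(net.species_ids, labels)
        g = nx.from_numpy_array(w)
        communities = [set(np.nonzero(np.array(labels) == c)[0])
                       for c in sorted(set(labels))]
        assert fn.modularity_q(net, part) == pytest.approx(
            nx.community.modularity(g, communities, weight="weight"))
        scaled = net_from_weights(w * 0.37)
        # rescaling-invariance requires weights <= 1; 0.37 keeps them valid
        assert fn.modularity_q(scaled, part) == pytest.approx(
            fn.modularity_q(net, part))


def test_greedy_two_triangles(two_triangles):
    part, q = fn.greedy_modularity(two_triangles)
    assert q == pytest.approx(0.5)
    assert part.n_communities == 2
    assert part.labels[:3] == (part.labels[0],) * 3
    assert part.labels[3:] == (part.labels[3],) * 3


def test_greedy_complete_graph_single_community():
    net = complete_net(5)
    part, q = fn.greedy_modularity(net)
    assert q == pytest.approx(0.0, abs=1e-12)
    assert max_modularity_oracle(net.weights) == pytest.approx(0.0, abs=1e-12)


def test_greedy_path_matches_exhaustive_oracle():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    net = net_from_weights(w)
    _, q = fn.greedy_modularity(net)
    assert q == pytest.approx(max_modularity_oracle(w))


def test_greedy_never_beats_oracle_and_is_deterministic():
    rng = np.random.default_rng(23)
    for _ in range(30):
        n = int(rng.integers(3, 8))
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        w[iu] = rng.uniform(0.1, 1, len(iu[0])) * (rng.random(len(iu[0])) < 0.6)
        w = w + w.T
        if w.sum() == 0:
            continue
        net = net_from_weights(w)
        part1, q1 = fn.greedy_modularity(net)
        part2, q2 = fn.greedy_modularity(net)
        assert part1.labels == part2.labels and q1 == q2
        assert q1 <= max_modularity_oracle(w) + 1e-10


def test_clustering_triangle_and_star():
    assert fn.weighted_global_clustering(complete_net(3)) == pytest.approx(1.0)
    assert fn.weighted_global_clustering(star_net(3)) == 0.0
    assert fn.weighted_global_clustering(complete_net(6, 0.3)) == pytest.approx(1.0)


def test_clustering_pendant_example_matches_triplet_enumeration():
    """Triangle AB=1, BC=0.5, AC=0.5 with pendant CD=1."""
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 0.5
    w[0, 2] = w[2, 0] = 0.5
    w[2, 3] = w[3, 2] = 1.0
    assert fn.weighted_global_clustering(net_from_weights(w)) == pytest.approx(
        clustering_oracle(w))


def test_clustering_matches_oracle_on_random_weighted_networks():
    rng = np.random.default_rng(5)
    checked = 0
    for _ in range(30):
        n = int(rng.integers(3, 9))
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        w[iu] = rng.uniform(0, 1, len(iu[0])) * (rng.random(len(iu[0])) < 0.6)
        w = w + w.T
        try:
            want = clustering_oracle(w)
        except ValueError:
            continue
        got = fn.weighted_global_clustering(net_from_weights(w))
        assert got == pytest.approx(want)
        checked += 1
    assert checked > 10


def test_clustering_undefined_without_triplets():
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    w[2, 3] = w[3, 2] = 1.0  # two disjoint dyads: no node has 2 neighbours
    with pytest.raises(fn.UndefinedMetricError):
        fn.weighted_global_clustering(net_from_weights(w))


def test_compute_all_metrics_toy(toy_fm):
    m = fn.compute_all_metrics(toy_fm)
    assert m.mean_richness_per_flock == pytest.approx(7 / 3)
    assert m.connectance == 1.0
    assert m.cv == pytest.approx(0.34641016)
    assert m.avg_degree_norm == 1.0
    assert 0.0 <= m.clustering <= 1.0
    assert -0.5 <= m.modularity_q <= 1.0


def test_partition_label_validation():
    with pytest.raises(ValueError):
        fn.Partition(("a", "b"), (0, 2))  # gap in labels
    with pytest.raises(ValueError):
        fn.Partition(("a", "b"), (0,))    # wrong length


def test_set_partition_oracle_counts_bell_numbers():
    # guard the oracle itself: Bell numbers B(3)=5, B(4)=15
    assert sum(1 for _ in set_partitions(3)) == 5
    assert sum(1 for _ in set_partitions(4)) == 15
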