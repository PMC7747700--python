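"""Dynamical network construction and suboptimal path enumeration."""

import networkx as nx
import numpy as np
import pytest

from allopath.allosteric_network import (
    ContactMap,
    DynamicalNetwork,
    build_network,
    contact_fractions,
    optimal_paths,
    path_histogram,
    suboptimal_paths,
)
from allopath.dynamics import CorrelationMatrix, correlation_matrix
from allopath.ensemble_io import Selection
from allopath.errors import SpecificationError
from allopath.synthetic_data import TrajectorySpec, make_correlated_trajectory

from conftest import coords_ensemble


def label(i):
    return ("A", i)


def make_net(edges):
    """DynamicalNetwork from (i, j, weight) tuples over integer nodes."""
    g = nx.Graph()
    for i, j, w in edges:
        g.add_edge(label(i), label(j), weight=float(w), correlation=np.exp(-w))
    return DynamicalNetwork(graph=g)


# ---------------------------------------------------------------------------
# contact fractions


def test_fixed_pair_within_cutoff_has_unit_fraction():
    frames = np.tile(np.array([[0, 0, 0], [3.0, 0, 0]], float), (10, 1, 1))
    cmap = contact_fractions(coords_ensemble(frames))
    assert cmap.F[0, 1] == 1.0


def test_exact_750_of_1000_frames_gives_0_75():
    frames = np.zeros((1000, 2, 3))
    frames[:, 1, 0] = 3.0
    frames[750:, 1, 0] = 6.0  # out of contact in the last 250 frames
    cmap = contact_fractions(coords_ensemble(frames))
    assert cmap.F[0, 1] == pytest.approx(0.75)
    corr = CorrelationMatrix(labels=cmap.labels, C=np.full((2, 2), 0.8))
    net = build_network(cmap, corr, exclude_sequence_neighbors=False)
    assert net.graph.has_edge(("A", 1), ("A", 2))


def test_far_pair_has_zero_fraction():
    frames = np.zeros((50, 2, 3))
    frames[:, 1, 0] = 10.0
    cmap = contact_fractions(coords_ensemble(frames))
    assert cmap.F[0, 1] == 0.0


def test_heavy_atom_mode_uses_closest_atoms():
    """Residues whose CAs are far but side atoms touch still count."""
    from conftest import build_ensemble, build_model

    rows = [("CA", "C", "ALA", 1, "A", (0, 0, 0)),
            ("CB", "C", "ALA", 1, "A", (3, 0, 0)),
            ("CA", "C", "ALA", 2, "A", (7, 0, 0)),
            ("CB", "C", "ALA", 2, "A", (4, 0, 0))]
    ens = build_ensemble([build_model(rows)])
    assert contact_fractions(ens, mode="heavy").F[0, 1] == 1.0
    assert contact_fractions(ens, mode="ca").F[0, 1] == 0.0


# ---------------------------------------------------------------------------
# network construction


def two_residue_inputs(F01, C01):
    labels = [("A", 1), ("A", 3)]  # non-adjacent in sequence
    F = np.array([[1.0, F01], [F01, 1.0]])
    C = np.array([[1.0, C01], [C01, 1.0]])
    return (ContactMap(labels=labels, F=F),
            CorrelationMatrix(labels=labels, C=C))


def test_unit_correlation_gives_zero_length():
    net = build_network(*two_residue_inputs(1.0, 1.0))
    assert net.graph[("A", 1)][("A", 3)]["weight"] == 0.0


def test_half_correlation_gives_log_two():
    net = build_network(*two_residue_inputs(0.9, 0.5))
    assert net.graph[("A", 1)][("A", 3)]["weight"] == pytest.approx(np.log(2))


def test_subthreshold_contact_admits_no_edge():
    net = build_network(*two_residue_inputs(0.74, 0.99))
    assert net.graph.number_of_edges() == 0


def test_zero_correlation_contact_warns_and_drops():
    with pytest.warns(UserWarning, match="zero correlation"):
        net = build_network(*two_residue_inputs(1.0, 0.0))
    assert net.graph.number_of_edges() == 0


def test_sequence_neighbors_excluded_by_default():
    labels = [("A", 1), ("A", 2)]
    F = np.ones((2, 2))
    C = np.full((2, 2), 0.9)
    np.fill_diagonal(C, 1.0)
    cmap = ContactMap(labels=labels, F=F)
    corr = CorrelationMatrix(labels=labels, C=C)
    assert build_network(cmap, corr).graph.number_of_edges() == 0
    assert build_network(cmap, corr,
                         exclude_sequence_neighbors=False).graph.number_of_edges() == 1


def test_label_mismatch_rejected():
    cmap, _ = two_residue_inputs(1.0, 0.5)
    corr = CorrelationMatrix(labels=[("A", 1), ("A", 9)], C=np.eye(2))
    with pytest.raises(SpecificationError):
        build_network(cmap, corr)


# ---------------------------------------------------------------------------
# shortest / suboptimal paths


def test_single_edge_distance():
    dist, _ = optimal_paths(make_net([(1, 2, 1.0)]))
    assert dist[label(1)][label(2)] == 1.0


def test_triangle_routes_through_cheap_edges():
    dist, pred = optimal_paths(make_net([(1, 2, 1.0), (2, 3, 1.0), (1, 3, 3.0)]))
    assert dist[label(1)][label(3)] == pytest.approx(2.0)
    assert pred[label(1)][label(3)] == label(2)


def random_network(rng, n_nodes, p_edge=0.45):
    g = nx.gnp_random_graph(n_nodes, p_edge, seed=int(rng.integers(2**31)))
    net = nx.Graph()
    net.add_nodes_from(label(i) for i in range(n_nodes))
    for u, v in g.edges:
        net.add_edge(label(u), label(v),
                     weight=float(rng.uniform(0.1, 3.0)), correlation=0.5)
    return DynamicalNetwork(graph=net)


def test_floyd_warshall_equals_dijkstra(rng):
    for _ in range(25):
        net = random_network(rng, 8)
        dist, _ = optimal_paths(net)
        for src in net.graph.nodes:
            dj = nx.single_source_dijkstra_path_length(net.graph, src,
                                                       weight="weight")
            for dst, d in dj.items():
                assert dist[src][dst] == pytest.approx(d, abs=1e-12)


def exhaustive_k_shortest(graph, source, sink, k):
    """Brute-force oracle: enumerate every simple path, sort, truncate."""
    paths = []
    for nodes in nx.all_simple_paths(graph, source, sink):
        length = sum(graph[u][v]["weight"] for u, v in zip(nodes, nodes[1:]))
        paths.append((round(length, 10), tuple(nodes)))
    paths.sort()
    return paths[:k]


def test_two_parallel_routes_ordered():
    net = make_net([(1, 2, 1.0), (2, 4, 1.0), (1, 3, 1.5), (3, 4, 1.5)])
    ps = suboptimal_paths(net, label(1), label(4), k=2)
    assert [p.length for p in ps.paths] == pytest.approx([2.0, 3.0])
    assert ps.paths[0].nodes == (label(1), label(2), label(4))


def test_k1_equals_floyd_warshall_optimum(rng):
    for _ in range(10):
        net = random_network(rng, 7)
        dist, _ = optimal_paths(net)
        nodes = sorted(net.graph.nodes)
        src, dst = nodes[0], nodes[-1]
        ps = suboptimal_paths(net, src, dst, k=1)
        if not ps.reachable:
            assert np.isinf(dist[src][dst])
            continue
        assert ps.optimal.length == pytest.approx(dist[src][dst], abs=1e-12)


def test_suboptimal_equals_bruteforce_enumeration(rng):
    """Yen-based top-k equals exhaustive simple-path enumeration (<= 8 nodes)."""
    for _ in range(40):
        n = int(rng.integers(4, 9))
        net = random_network(rng, n)
        src, dst = label(0), label(n - 1)
        ps = suboptimal_paths(net, src, dst, k=12)
        oracle = exhaustive_k_shortest(net.graph, src, dst, 12)
        assert [(round(p.length, 10), p.nodes) for p in ps.paths] == oracle


def test_equal_length_paths_ordered_lexicographically():
    net = make_net([(1, 2, 1.0), (2, 5, 1.0), (1, 4, 1.0), (4, 5, 1.0)])
    ps = suboptimal_paths(net, label(1), label(5), k=2)
    assert ps.paths[0].nodes == (label(1), label(2), label(5))
    assert ps.paths[1].nodes == (label(1), label(4), label(5))


def test_unreachable_sink_flagged():
    net = make_net([(1, 2, 1.0)])
    net.graph.add_node(label(9))
    ps = suboptimal_paths(net, label(1), label(9), k=5)
    assert not ps.reachable and ps.paths == []


def test_path_lengths_nondecreasing(rng):
    net = random_network(rng, 8, p_edge=0.6)
    ps = suboptimal_paths(net, label(0), label(7), k=30)
    if ps.reachable:
        assert np.all(np.diff(ps.lengths) >= -1e-12)


# ---------------------------------------------------------------------------
# histogram


def test_three_paths_one_bin():
    net = make_net([(1, 2, 1.0), (2, 4, 1.0), (1, 3, 1.5), (3, 4, 1.5),
                    (2, 3, 0.2)])
    ps = suboptimal_paths(net, label(1), label(4), k=3)
    hist = path_histogram(ps, bins=[0.0, 10.0])
    assert hist.counts.tolist() == [3]


def test_histogram_counts_sum_to_paths(rng):
    net = random_network(rng, 8, p_edge=0.6)
    ps = suboptimal_paths(net, label(0), label(7), k=25)
    hist = path_histogram(ps, bins=7)
    assert hist.counts.sum() == len(ps.paths)


def test_uncovering_bin_edges_rejected():
    net = make_net([(1, 2, 2.0)])
    ps = suboptimal_paths(net, label(1), label(2), k=1)
    with pytest.raises(SpecificationError):
        path_histogram(ps, bins=[0.0, 1.0])


# ---------------------------------------------------------------------------
# planted corridor recovery


def corridor_pathset(rho, n_frames=1200, seed=21, k=50):
    spec = TrajectorySpec(corridor_rho=rho, n_frames=n_frames, seed=seed)
    traj = make_correlated_trajectory(spec)
    corr = correlation_matrix(traj, Selection(name="CA"), superpose=False)
    cmap = contact_fractions(traj)
    net = build_network(cmap, corr)
    return spec, suboptimal_paths(net, ("A", spec.source), ("A", spec.sink), k=k)


def test_optimal_path_equals_planted_corridor():
    spec, ps = corridor_pathset(0.9)
    assert [r for _, r in ps.optimal.nodes] == list(spec.corridor)


def test_stronger_corridor_shortens_optimal_path():
    lengths = [corridor_pathset(rho)[1].optimal.length
               for rho in (0.5, 0.7, 0.9)]
    assert lengths[0] > lengths[1] > lengths[2]


def test_stronger_corridor_shifts_path_population():
    _, weak = corridor_pathset(0.6, k=100)
    _, strong = corridor_pathset(0.9, k=100)
    assert strong.lengths.mean() < weak.lengths.mean()
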