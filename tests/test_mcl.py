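"""Network construction and Markov clustering correctness."""
import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfclust.composites import PairFrequencyTable
from tfclust.mcl import (
    ClusterSet,
    MCLParams,
    build_network,
    cluster_network,
    expand,
    extract_clusters,
    inflate,
    run_mcl,
    to_markov,
)


def naive_mcl(m, r=2.0, tol=1e-6, max_iter=200):
    """Independent flow-simulation oracle: plain-python Expand/Inflate loop."""
    m = [row[:] for row in m]
    n = len(m)
    for _ in range(max_iter):
        # expand: cubic-time matrix product
        prod = [[sum(m[i][k] * m[k][j] for k in range(n)) for j in range(n)]
                for i in range(n)]
        # inflate: entrywise power then row renormalization
        powed = [[prod[i][j] ** r for j in range(n)] for i in range(n)]
        nxt = [[powed[i][j] / sum(powed[i]) for j in range(n)] for i in range(n)]
        delta = max(abs(nxt[i][j] - m[i][j]) for i in range(n) for j in range(n))
        m = nxt
        if delta < tol:
            break
    return m


def naive_clusters(m, nodes, eps=1e-6):
    """Read clusters from a converged matrix by connected support overlap."""
    n = len(nodes)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if m[i][j] > eps:
                g.add_edge(i, j)
    return sorted(
        sorted(nodes[i] for i in comp) for comp in nx.connected_components(g)
    )


def random_stochastic(rng, n):
    m = rng.random((n, n)) + 0.05
    return m / m.sum(axis=1, keepdims=True)


class TestBuildNetwork:
    MAPPING = {"ab": ("a", "b"), "ac": ("a", "c"), "ba": ("b", "a"),
               "aa": ("a", "a")}

    def test_edges_carry_frequencies(self):
        net = build_network(PairFrequencyTable("s", {"ab": 3, "ac": 1}),
                            self.MAPPING)
        assert set(net.nodes) == {"a", "b", "c"}
        assert net["a"]["b"]["weight"] == 3
        assert net["a"]["c"]["weight"] == 1

    def test_empty_table_gives_empty_network(self):
        net = build_network(PairFrequencyTable("s", {}), self.MAPPING)
        assert net.number_of_nodes() == 0

    def test_same_unordered_pair_sums_weights(self):
        net = build_network(PairFrequencyTable("s", {"ab": 3, "ba": 2}),
                            self.MAPPING)
        assert net["a"]["b"]["weight"] == 5

    def test_homotypic_pair_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            net = build_network(PairFrequencyTable("s", {"aa": 4, "ab": 1}),
                                self.MAPPING)
        assert not net.has_edge("a", "a")
        assert "homotypic" in caplog.text

    def test_unmapped_pair_rejected(self):
        with pytest.raises(KeyError):
            build_network(PairFrequencyTable("s", {"zz": 1}), self.MAPPING)


class TestMarkovMatrix:
    def test_single_edge_with_matching_self_loop(self):
        net = nx.Graph()
        net.add_edge("a", "b", weight=5.0)
        m, nodes = to_markov(net, MCLParams(self_loop_weight=5.0))
        assert nodes == ["a", "b"]
        assert np.allclose(m, [[0.5, 0.5], [0.5, 0.5]])

    def test_star_row_normalization(self):
        net = nx.Graph()
        net.add_edge("a", "b", weight=1.0)
        net.add_edge("a", "c", weight=1.0)
        m, nodes = to_markov(net, MCLParams(self_loop_weight=1.0))
        assert np.allclose(m[nodes.index("a")], [1 / 3, 1 / 3, 1 / 3])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rows_always_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        net = nx.gnm_random_graph(6, 9, seed=seed)
        if net.number_of_edges() == 0:
            net.add_edge(0, 1)
        for u, v in net.edges:
            net[u][v]["weight"] = float(rng.integers(1, 9))
        net = nx.relabel_nodes(net, {i: f"n{i}" for i in net.nodes})
        m, _ = to_markov(net, MCLParams())
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)


class TestExpandInflate:
    def test_expand_identity(self):
        eye = np.eye(3)
        assert np.allclose(expand(eye), eye)

    def test_expand_idempotent_doubly_stochastic_block(self):
        m = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert np.allclose(expand(m), m)

    def test_expand_matches_cubic_time_product(self):
        rng = np.random.default_rng(2)
        m = random_stochastic(rng, 4)
        brute = [[sum(m[i][k] * m[k][j] for k in range(4)) for j in range(4)]
                 for i in range(4)]
        assert np.allclose(expand(m), brute, atol=1e-9)

    @pytest.mark.parametrize(
        "row, r, expected",
        [
            ([1.0, 0.0], 2.0, [1.0, 0.0]),
            ([0.5, 0.5], 2.0, [0.5, 0.5]),
            ([0.8, 0.2], 2.0, [0.64 / 0.68, 0.04 / 0.68]),
        ],
    )
    def test_inflate_hand_examples(self, row, r, expected):
        out = inflate(np.array([row]), r)
        assert np.allclose(out, [expected])

    def test_inflate_preserves_row_sums(self):
        rng = np.random.default_rng(3)
        m = random_stochastic(rng, 5)
        assert np.allclose(inflate(m, 2.0).sum(axis=1), 1.0, atol=1e-9)

    def test_all_zero_row_after_pruning_rejected(self):
        with pytest.raises(ValueError):
            inflate(np.array([[1e-10, 1e-10]]), 2.0, prune=1e-9)

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            inflate(np.eye(2), 1.0)
        with pytest.raises(ValueError):
            MCLParams(inflation=0.9)


def triangles_graph():
    net = nx.Graph()
    for tri in (("a", "b", "c"), ("x", "y", "z")):
        for i in range(3):
            net.add_edge(tri[i], tri[(i + 1) % 3], weight=1.0)
    return net


def barbell_graph(bridge=0.1):
    net = nx.Graph()
    for grp in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
        for u, v in itertools.combinations(grp, 2):
            net.add_edge(u, v, weight=1.0)
    net.add_edge("a1", "b1", weight=bridge)
    return net


class TestRunMCL:
    def test_disjoint_triangles_make_two_clusters(self):
        _, cs = cluster_network(triangles_graph())
        assert cs.clusters == [["a", "b", "c"], ["x", "y", "z"]]

    def test_single_edge_collapses_to_one_cluster(self):
        net = nx.Graph()
        net.add_edge("a", "b", weight=5.0)
        _, cs = cluster_network(net)
        assert cs.clusters == [["a", "b"]]

    def test_weak_bridge_barbell_splits_at_bridge(self):
        _, cs = cluster_network(barbell_graph(), MCLParams(inflation=2.0))
        assert cs.clusters == [["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]]

    @pytest.mark.parametrize("graph_fn", [triangles_graph, barbell_graph])
    def test_matches_independent_flow_simulation(self, graph_fn):
        net = graph_fn()
        params = MCLParams(inflation=2.0)
        m0, nodes = to_markov(net, params)
        _, cs = run_mcl(m0, params, nodes=nodes)
        oracle = naive_clusters(naive_mcl(m0.tolist()), nodes)
        assert cs.clusters == oracle

    def test_converged_matrix_is_row_stochastic(self):
        m0, nodes = to_markov(barbell_graph(), MCLParams())
        mc, _ = run_mcl(m0, MCLParams(), nodes=nodes)
        assert np.allclose(mc.sum(axis=1), 1.0, atol=1e-9)

    def test_non_stochastic_input_rejected(self):
        with pytest.raises(ValueError):
            run_mcl(np.array([[0.5, 0.4], [0.5, 0.5]]))

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_permutation_invariance_of_clusters(self, seed):
        rng = np.random.default_rng(seed)
        net = barbell_graph(bridge=float(rng.uniform(0.05, 0.3)))
        _, cs = cluster_network(net)
        relabeled = nx.relabel_nodes(net, {n: f"z_{n}" for n in net.nodes})
        _, cs2 = cluster_network(relabeled)
        stripped = sorted(sorted(n.removeprefix("z_") for n in c)
                          for c in cs2.clusters)
        assert sorted(cs.clusters) == stripped

    def test_disconnected_components_never_merge(self):
        net = nx.union(triangles_graph(),
                       nx.relabel_nodes(barbell_graph(), lambda n: f"k{n}"))
        _, cs = cluster_network(net)
        comp_of = {}
        for i, comp in enumerate(nx.connected_components(net)):
            for n in comp:
                comp_of[n] = i
        for c in cs.clusters:
            assert len({comp_of[n] for n in c}) == 1

    def test_clusters_partition_node_set(self):
        net = barbell_graph()
        _, cs = cluster_network(net)
        nodes = [n for c in cs.clusters for n in c]
        assert sorted(nodes) == sorted(net.nodes)


class TestExtractClusters:
    def test_block_diagonal_uniform_blocks(self):
        m = np.zeros((4, 4))
        m[:2, :2] = 0.5
        m[2:, 2:] = 0.5
        assert sorted(extract_clusters(m, ["a", "b", "c", "d"])) == [
            ["a", "b"], ["c", "d"]
        ]

    def test_single_attractor_column(self):
        m = np.zeros((3, 3))
        m[:, 0] = 1.0
        assert extract_clusters(m, ["a", "b", "c"]) == [["a", "b", "c"]]

    def test_flow_tie_breaks_lexicographically(self, caplog):
        # node d sends equal flow to attractors a and c -> they merge through
        # the shared supporter, and the tie is logged
        m = np.array(
            [
                [1.0, 0.0, 0.0, 0.0],
                [0.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.0],
                [0.5, 0.0, 0.5, 0.0],
            ]
        )
        with caplog.at_level("INFO"):
            clusters = extract_clusters(m, ["a", "b", "c", "d"])
        assert ["a", "c", "d"] in clusters and ["b"] in clusters

    def test_cluster_set_rejects_duplicate_assignment(self):
        with pytest.raises(ValueError):
            ClusterSet(stage="s", clusters=[["a", "b"], ["b"]])
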