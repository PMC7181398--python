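"""Correlation matrix, network thresholding and MCL clustering.

The MCL implementation is checked against an independent dense-numpy
reference written here from the algorithm definition (expansion by matrix
power, inflation by entry-wise power with column renormalization, attractor
read-off), using a different matrix representation and a different
component extraction (networkx) than the package's sparse implementation.
"""

import numpy as np
import pandas as pd
import pytest

from methaniche.data import AbundanceTable, FeatureAnnotation
from methaniche.network import (
    ClusterAssignment,
    CoabundanceNetwork,
    build_network,
    cluster_summary,
    mcl_cluster,
    pearson_matrix,
)


def _corr(ids, mat):
    from methaniche.network import CorrelationMatrix

    return CorrelationMatrix(ids, np.asarray(mat, float))


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------


class TestPearson:
    def test_copy_and_negation(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(5, 10, size=8)
        values = pd.DataFrame(
            [base, base.copy(), 2 * base.mean() - base],
            index=["f", "copy", "neg"],
            columns=[f"s{i}" for i in range(8)],
        )
        corr = pearson_matrix(AbundanceTable(values, "genus", "counts"))
        f = corr.to_frame()
        assert f.loc["f", "copy"] == pytest.approx(1.0, abs=1e-12)
        assert f.loc["f", "neg"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        """3 features x 5 samples against the raw product-moment formula."""
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, size=(3, 5))
        values = pd.DataFrame(x, index=list("abc"), columns=[f"s{i}" for i in range(5)])
        corr = pearson_matrix(AbundanceTable(values, "gene", "counts")).values
        for i in range(3):
            for j in range(3):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert corr[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_feature_named(self):
        values = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"], columns=list("abc")
        )
        with pytest.raises(ValueError, match="flat"):
            pearson_matrix(AbundanceTable(values, "gene", "counts"))


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------


class TestBuildNetwork:
    def test_threshold_boundaries(self):
        ids = list("abcd")
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 0.71
        m[2, 3] = m[3, 2] = 0.69
        m[0, 2] = m[2, 0] = -0.95
        net = build_network(_corr(ids, m), threshold=0.70)
        pairs = set(map(tuple, net.edges[["node_a", "node_b"]].to_numpy()))
        assert ("a", "b") in pairs
        assert ("c", "d") not in pairs
        assert not any("c" in p and "a" in p for p in pairs)  # negative r never an edge

    def test_exact_threshold_inclusive_vs_strict(self):
        ids = ["a", "b"]
        m = np.array([[1.0, 0.70], [0.70, 1.0]])
        assert build_network(_corr(ids, m), 0.70).n_edges == 1
        assert build_network(_corr(ids, m), 0.70, inclusive=False).n_edges == 0

    def test_isolated_node_dropped(self):
        ids = list("abc")
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.9
        m[0, 2] = m[2, 0] = 0.5
        net = build_network(_corr(ids, m), 0.70)
        assert net.dropped_nodes == ["c"]
        assert sorted(net.nodes) + ["c"] == list("abc")

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            build_network(_corr(["a", "b"], np.eye(2)), threshold=1.5)


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------


def dense_mcl_reference(adj: np.ndarray, inflation=2.2, expansion=2,
                        prune=1e-5, tol=1e-8, max_iter=200) -> list[set[int]]:
    """Independent dense MCL: returns the partition as a list of node sets."""
    import networkx as nx

    n = adj.shape[0]
    m = adj.astype(float).copy()
    np.fill_diagonal(m, 1.0)
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m.copy()
        m = np.linalg.matrix_power(m, expansion)
        m = m**inflation
        m /= m.sum(axis=0, keepdims=True)
        m[m < prune] = 0.0
        m /= m.sum(axis=0, keepdims=True)
        if np.abs(m - prev).max() < tol:
            break
    attractors = np.where(np.diag(m) > 0)[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in attractors:
        for j in np.where(m[i] > 0)[0]:
            g.add_edge(i, j)
    return [set(c) for c in nx.connected_components(g)]


def _net_from_adjacency(adj: np.ndarray) -> CoabundanceNetwork:
    n = adj.shape[0]
    ids = [f"n{i}" for i in range(n)]
    ii, jj = np.triu_indices(n, k=1)
    mask = adj[ii, jj] > 0
    edges = pd.DataFrame(
        {
            "node_a": [ids[i] for i in ii[mask]],
            "node_b": [ids[j] for j in jj[mask]],
            "weight": adj[ii, jj][mask],
        }
    )
    return CoabundanceNetwork(nodes=ids, edges=edges, threshold=0.7)


def _random_block_graph(rng, n_nodes):
    """Planted-partition weighted graph: dense blocks, sparse bridges."""
    sizes = []
    remaining = n_nodes
    while remaining > 0:
        s = int(rng.integers(8, 30))
        sizes.append(min(s, remaining))
        remaining -= s
    adj = np.zeros((n_nodes, n_nodes))
    start = 0
    for s in sizes:
        for i in range(start, start + s):
            for j in range(i + 1, start + s):
                if rng.random() < 0.7:
                    adj[i, j] = adj[j, i] = rng.uniform(0.7, 1.0)
        start += s
    # a few weak bridges between consecutive blocks
    start = 0
    for s in sizes[:-1]:
        i = int(rng.integers(start, start + s))
        j = int(rng.integers(start + s, min(start + s + 5, n_nodes)))
        adj[i, j] = adj[j, i] = 0.71
        start += s
    # ensure no isolated node (degree >= 1 network invariant)
    for i in range(n_nodes):
        if adj[i].sum() == 0:
            j = (i + 1) % n_nodes
            adj[i, j] = adj[j, i] = 0.75
    return adj


class TestMcl:
    def test_two_cliques_with_bridge(self):
        adj = np.zeros((8, 8))
        adj[:4, :4] = 0.9
        adj[4:, 4:] = 0.9
        np.fill_diagonal(adj, 0.0)
        adj[3, 4] = adj[4, 3] = 0.71
        assignment = mcl_cluster(_net_from_adjacency(adj))
        labels = assignment.labels
        assert assignment.n_clusters == 2
        assert len(set(labels.iloc[:4])) == 1
        assert len(set(labels.iloc[4:])) == 1
        assert labels.iloc[0] != labels.iloc[7]
        # agrees with the independent dense reference
        ref = dense_mcl_reference(adj)
        got = [set(int(n[1:]) for n in assignment.members(c))
               for c in range(1, assignment.n_clusters + 1)]
        assert sorted(map(sorted, ref)) == sorted(map(sorted, got))

    def test_isolated_triangle_single_cluster(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = adj[0, 2] = adj[2, 0] = adj[1, 2] = adj[2, 1] = 0.8
        assignment = mcl_cluster(_net_from_adjacency(adj))
        assert assignment.n_clusters == 1
        assert assignment.sizes()[1] == 3

    def test_clusters_never_span_components(self):
        adj = np.zeros((7, 7))
        adj[0:3, 0:3] = 0.85
        adj[3:7, 3:7] = 0.85
        np.fill_diagonal(adj, 0)
        assignment = mcl_cluster(_net_from_adjacency(adj))
        left = {assignment.labels.iloc[i] for i in range(3)}
        right = {assignment.labels.iloc[i] for i in range(3, 7)}
        assert left.isdisjoint(right)

    def test_matches_dense_reference_on_random_graphs(self):
        """Partition-for-partition equivalence on 20 random block graphs."""
        rng = np.random.default_rng(2024)
        for trial in range(20):
            n = int(rng.integers(50, 201))
            adj = _random_block_graph(rng, n)
            assignment = mcl_cluster(_net_from_adjacency(adj))
            ref = dense_mcl_reference(adj)
            got = [
                set(int(x[1:]) for x in assignment.members(c))
                for c in range(1, assignment.n_clusters + 1)
            ]
            assert sorted(map(sorted, ref)) == sorted(map(sorted, got)), f"trial {trial}"

    def test_partition_property_and_numbering(self):
        rng = np.random.default_rng(5)
        adj = _random_block_graph(rng, 60)
        assignment = mcl_cluster(_net_from_adjacency(adj))
        assert assignment.sizes().sum() == 60
        sizes = assignment.sizes()
        assert list(sizes.index) == list(range(1, assignment.n_clusters + 1))
        assert (sizes.diff().dropna() <= 0).all()  # numbered by decreasing size

    def test_column_stochastic_at_every_normalize(self, monkeypatch):
        import methaniche.network as netmod

        sums_seen = []
        original = netmod._column_normalize

        def recording(m):
            out = original(m)
            sums_seen.append(np.asarray(out.sum(axis=0)).ravel())
            return out

        monkeypatch.setattr(netmod, "_column_normalize", recording)
        adj = _random_block_graph(np.random.default_rng(9), 40)
        netmod.mcl_cluster(_net_from_adjacency(adj))
        assert len(sums_seen) > 2
        for s in sums_seen:
            assert np.allclose(s, 1.0, atol=1e-10)


# ---------------------------------------------------------------------------
# Cluster summary
# ---------------------------------------------------------------------------


def test_cluster_summary_counts_and_abundance():
    values = pd.DataFrame(
        np.array([[10.0, 10], [20, 20], [30, 30], [15, 15], [25, 25]]),
        index=["g1", "g2", "g3", "t1", "t2"],
        columns=["a", "b"],
    )
    kind = pd.Series(["gene"] * 3 + ["genus"] * 2, index=values.index)
    table = AbundanceTable(values, kind, "counts")
    annotation = FeatureAnnotation(
        pd.DataFrame(
            {
                "feature_id": ["g1", "g2", "g3", "t1", "t2"],
                "label": ["K1", "K2", "K3", "Prevotella", "Methanobrevibacter"],
                "domain": ["gene", "gene", "gene", "bacteria", "archaea"],
            }
        )
    )
    assignment = ClusterAssignment(
        labels=pd.Series([1, 1, 2, 1, 2], index=values.index)
    )
    report = cluster_summary(assignment, annotation, table)
    c1 = report[report["cluster"] == 1].iloc[0]
    assert c1["n_gene"] == 2 and c1["n_bacteria"] == 1
    assert c1["abundance_bacteria"] == pytest.approx(15.0)


def test_cluster_summary_unknown_domain():
    values = pd.DataFrame([[1.0], [2.0]], index=["x", "y"], columns=["a"])
    table = AbundanceTable(values, "genus", "counts")
    annotation = FeatureAnnotation(
        pd.DataFrame({"feature_id": ["x"], "label": ["X"], "domain": ["bacteria"]})
    )
    assignment = ClusterAssignment(labels=pd.Series([1, 1], index=["x", "y"]))
    report = cluster_summary(assignment, annotation, table)
    assert report.iloc[0]["n_unknown"] == 1
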