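"""Co-abundance network construction and Markov (MCL) clustering.

Features whose abundance profiles correlate above a positive Pearson
threshold (default r >= 0.70) are linked in an undirected weighted graph;
features correlated with nothing are dropped from the network. The graph is
then partitioned by the Markov Cluster algorithm: simulate flow on the graph
by alternately squaring ("expansion") and entry-wise powering + column
renormalization ("inflation", default 2.2) of a column-stochastic matrix;
the limit flow concentrates on within-cluster attractors, whose basins are
read off as clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .data import AbundanceTable, FeatureAnnotation

__all__ = [
    "CorrelationMatrix",
    "CoabundanceNetwork",
    "ClusterAssignment",
    "pearson_matrix",
    "build_network",
    "mcl_cluster",
    "cluster_summary",
]


@dataclass
class CorrelationMatrix:
    """Symmetric feature-by-feature correlation matrix with a method tag."""

    feature_ids: list[str]
    values: np.ndarray
    method: str = "pearson"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        p = len(self.feature_ids)
        if v.shape != (p, p):
            raise ValueError(f"correlation matrix shape {v.shape} != ({p}, {p})")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9, rtol=0):
            raise ValueError("correlation diagonal must be 1")
        if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("correlations outside [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.feature_ids)


@dataclass
class CoabundanceNetwork:
    """Thresholded positive-correlation graph.

    ``nodes`` are the features retaining at least one edge; features whose
    best off-diagonal correlation fell below the threshold are recorded in
    ``dropped_nodes``.
    """

    nodes: list[str]
    edges: pd.DataFrame  # columns: node_a, node_b, weight
    threshold: float
    dropped_nodes: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency over ``nodes`` (no self-loops)."""
        index = {n: i for i, n in enumerate(self.nodes)}
        i = self.edges["node_a"].map(index).to_numpy()
        j = self.edges["node_b"].map(index).to_numpy()
        w = self.edges["weight"].to_numpy(float)
        n = len(self.nodes)
        a = sp.coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n))
        return a.tocsr()

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(
            self.edges[["node_a", "node_b", "weight"]].itertuples(index=False, name=None)
        )
        return g

    def write_edge_list(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


@dataclass
class ClusterAssignment:
    """Partition of network nodes into clusters numbered by decreasing size."""

    labels: pd.Series  # node -> cluster id (1-based)
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        ids = np.sort(self.labels.unique())
        if len(ids) and (ids[0] != 1 or ids[-1] != len(ids)):
            raise ValueError("cluster ids must be contiguous from 1")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def write_tsv(self, path) -> None:
        self.labels.rename("cluster").to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------


def pearson_matrix(table: AbundanceTable) -> CorrelationMatrix:
    """Product-moment correlation between all feature pairs across samples."""
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    x = table.values.to_numpy(float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = table.values.index[sd == 0][0]
        raise ValueError(f"constant feature {bad!r}; remove constant features first")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(table.feature_ids, r, "pearson")


def build_network(
    corr: CorrelationMatrix,
    threshold: float = 0.70,
    inclusive: bool = True,
) -> CoabundanceNetwork:
    """Keep edges with r >= threshold (or strictly > with ``inclusive=False``).

    Negative correlations never form edges. Nodes with no surviving edge are
    moved to ``dropped_nodes``.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    r = corr.values
    p = len(corr.feature_ids)
    iu = np.triu_indices(p, k=1)
    mask = r[iu] >= threshold if inclusive else r[iu] > threshold
    ii, jj = iu[0][mask], iu[1][mask]
    ids = np.asarray(corr.feature_ids, dtype=object)
    edges = pd.DataFrame(
        {"node_a": ids[ii], "node_b": ids[jj], "weight": r[iu][mask]}
    )
    connected = np.zeros(p, bool)
    connected[ii] = True
    connected[jj] = True
    return CoabundanceNetwork(
        nodes=list(ids[connected]),
        edges=edges,
        threshold=threshold,
        dropped_nodes=list(ids[~connected]),
    )


def _column_normalize(m: sp.csr_matrix) -> sp.csr_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return m @ sp.diags(1.0 / sums)


def mcl_cluster(
    network: CoabundanceNetwork,
    inflation: float = 2.2,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ClusterAssignment:
    """Markov Cluster algorithm on the co-abundance graph.

    Adds a self-loop of weight 1 to every node, column-normalizes, then
    iterates expansion (matrix power), inflation (entry-wise power followed
    by column renormalization) and pruning of entries below ``prune_below``
    until the matrix change falls under ``tol``. Clusters are the connected
    components of the limit matrix's attractor structure: rows retaining
    their own diagonal mass are attractors, and every node joins the
    attractors present in its column. Deterministic given node order.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    n = network.n_nodes
    m = network.adjacency().tolil()
    m.setdiag(1.0)
    m = _column_normalize(m.tocsr())

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m.copy()
        # expand
        for _ in range(expansion - 1):
            m = m @ m
        # inflate
        m = m.power(inflation)
        m = _column_normalize(m)
        # prune tiny entries, then renormalize
        m.data[m.data < prune_below] = 0.0
        m.eliminate_zeros()
        m = _column_normalize(m)
        diff = abs(m - prev)
        if diff.nnz == 0 or diff.max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {max_iter} iterations; "
            "clusters taken from the last iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    labels = _clusters_from_limit(m.tocsr(), n)
    return _renumber(labels, network.nodes, converged, it)


def _clusters_from_limit(m: sp.csr_matrix, n: int) -> np.ndarray:
    """Read cluster labels off a (near-)limit MCL matrix."""
    diag = m.diagonal()
    attractor = diag > 0
    if not attractor.any():
        # degenerate non-converged state: fall back to argmax row per column
        attractor[np.asarray(m.argmax(axis=0)).ravel()] = True
    # bipartite structure: connect attractor row i to every column j it serves
    coo = m.tocoo()
    keep = attractor[coo.row]
    g = sp.coo_matrix(
        (np.ones(keep.sum()), (coo.row[keep], coo.col[keep])), shape=(n, n)
    )
    _, comp = connected_components(g + g.T, directed=False)
    # nodes never touched by an attractor (isolated in the limit) keep their
    # own component id, i.e. become singletons — already handled by csgraph.
    return comp


def _renumber(
    comp: np.ndarray, nodes: list[str], converged: bool, n_iter: int
) -> ClusterAssignment:
    """Relabel components as 1..K by decreasing size (ties: first member)."""
    series = pd.Series(comp, index=nodes)
    sizes = series.value_counts()
    order = sorted(
        sizes.index, key=lambda c: (-sizes[c], int(np.argmax(comp == c)))
    )
    mapping = {c: k + 1 for k, c in enumerate(order)}
    return ClusterAssignment(
        labels=series.map(mapping), converged=converged, n_iterations=n_iter
    )


def cluster_summary(
    assignment: ClusterAssignment,
    annotation: FeatureAnnotation,
    table: AbundanceTable,
) -> pd.DataFrame:
    """Per-cluster composition: counts by domain and summed mean abundance.

    Mirrors the field's reporting style ("the cluster contains N genes and M
    genera, archaea making up X% of total abundance"). Unannotated nodes are
    counted under domain ``unknown``.
    """
    domain = annotation.domain_of()
    mean_ab = table.values.mean(axis=1)
    rows = []
    for c in range(1, assignment.n_clusters + 1):
        members = assignment.members(c)
        doms = pd.Series(
            [domain.get(m, "unknown") for m in members], index=members, dtype=object
        )
        counts = doms.value_counts().to_dict()
        abund = {
            f"abundance_{d}": float(mean_ab.reindex(doms.index[doms == d]).fillna(0).sum())
            for d in doms.unique()
        }
        rows.append(
            {
                "cluster": c,
                "size": len(members),
                **{f"n_{d}": int(v) for d, v in counts.items()},
                **abund,
            }
        )
    return pd.DataFrame(rows).fillna(0)
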