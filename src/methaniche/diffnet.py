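"""Separate co-abundance networks per emitter group and their comparison.

The pooled pipeline (correlation threshold 0.70, MCL clustering) is re-run
on the HME and LME sample subsets separately. Clusters are matched across
the two networks by Jaccard overlap, marker features (e.g. the dominant
methanogens) locate the "methanogenesis" cluster in each, and the matched
pair is summarized as a Venn triple (shared / only-A / only-B) plus a
hypergeometric overlap-enrichment test. Per-feature group differences are
Welch t-tests with an unadjusted P < 0.05 flag (Benjamini-Hochberg
adjusted values are reported alongside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import AbundanceTable, SampleMetadata
from .discriminate import EmitterGrouping
from .network import ClusterAssignment, CoabundanceNetwork, build_network, mcl_cluster, pearson_matrix

__all__ = [
    "GroupComparison",
    "subgroup_network",
    "locate_cluster_by_markers",
    "overlap_enrichment",
    "venn_counts",
    "node_differential",
    "compare_group_networks",
]


def subgroup_network(
    table: AbundanceTable,
    metadata: SampleMetadata,
    grouping: EmitterGrouping,
    group: str,
    threshold: float = 0.70,
    inflation: float = 2.2,
) -> tuple[CoabundanceNetwork, ClusterAssignment]:
    """Network + MCL clustering restricted to one emitter group's samples.

    Features that become constant within the subgroup are removed before
    correlation (they cannot carry a co-abundance signal there).
    """
    animals = [a for a in table.sample_ids if a in set(grouping.members(group))]
    if len(animals) < 4:
        raise ValueError(f"group {group!r} has {len(animals)} samples; need >= 4")
    sub = table.subset_samples(animals)
    sd = sub.values.std(axis=1)
    sub = sub.subset_features(sub.values.index[sd > 0])
    corr = pearson_matrix(sub)
    net = build_network(corr, threshold=threshold)
    assignment = mcl_cluster(net, inflation=inflation)
    return net, assignment


def locate_cluster_by_markers(
    assignment: ClusterAssignment, markers: list[str]
) -> int:
    """Cluster holding the plurality of the marker features.

    Ties resolve to the lowest cluster id with a warning. Errors when no
    marker is present in the assignment at all.
    """
    present = [m for m in markers if m in assignment.labels.index]
    if not present:
        raise ValueError("none of the marker features are in the clustering")
    counts = assignment.labels.loc[present].value_counts()
    top = counts[counts == counts.max()]
    if len(top) > 1:
        warnings.warn(
            f"marker plurality tie between clusters {sorted(top.index)}; "
            "taking the lowest id",
            RuntimeWarning,
            stacklevel=2,
        )
    return int(min(top.index))


def overlap_enrichment(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> dict[str, float]:
    """Upper-tail hypergeometric probability of the observed overlap.

    Drawing |A| nodes from the universe with |B| marked as successes,
    p = P(X >= k) for k = |A ∩ B|.
    """
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be contained in the universe")
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(set_b), len(set_a)))
    return {"k": k, "p_hyper": min(p, 1.0)}


def venn_counts(set_a: set[str], set_b: set[str]) -> tuple[int, int, int]:
    """(shared, only in A, only in B)."""
    return (len(set_a & set_b), len(set_a - set_b), len(set_b - set_a))


def node_differential(
    table: AbundanceTable, grouping: EmitterGrouping, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch t-test per feature between the two emitter groups.

    Returns t, unadjusted p with its < alpha flag, and BH-adjusted p.
    Features constant in both groups get p = 1.
    """
    from statsmodels.stats.multitest import multipletests

    a = table.subset_samples(
        [s for s in table.sample_ids if s in set(grouping.members("HME"))]
    ).values.to_numpy()
    b = table.subset_samples(
        [s for s in table.sample_ids if s in set(grouping.members("LME"))]
    ).values.to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant features are a handled degenerate case (p set to 1 below)
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = np.isnan(p)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "significant": p < alpha,
            "p_adjusted": p_adj,
        },
        index=table.feature_ids,
    )


@dataclass
class GroupComparison:
    """Cross-network cluster matching plus the marker-cluster Venn."""

    matches: pd.DataFrame  # cluster_a, best_cluster_b, jaccard, k, sizes, p, p_adj
    marker_cluster_a: int | None
    marker_cluster_b: int | None
    venn: tuple[int, int, int]  # shared, only_A, only_B
    differential: pd.DataFrame


def compare_group_networks(
    table: AbundanceTable,
    metadata: SampleMetadata,
    grouping: EmitterGrouping,
    markers: list[str] | None = None,
    threshold: float = 0.70,
    inflation: float = 2.2,
) -> GroupComparison:
    """Run both subgroup networks and compare their clusterings.

    Clusters of network A (HME) are greedily matched to network B (LME) by
    maximum Jaccard; each matched pair gets a hypergeometric overlap p-value
    (universe = features present in either network) with BH adjustment
    across pairs. When ``markers`` are given, the marker-bearing cluster is
    located in each network and its node sets are reduced to a Venn triple.
    """
    from statsmodels.stats.multitest import multipletests

    _, assign_a = subgroup_network(table, metadata, grouping, "HME", threshold, inflation)
    _, assign_b = subgroup_network(table, metadata, grouping, "LME", threshold, inflation)
    universe = set(assign_a.labels.index) | set(assign_b.labels.index)

    rows = []
    for ca in range(1, assign_a.n_clusters + 1):
        set_a = set(assign_a.members(ca))
        best = (0.0, None)
        for cb in range(1, assign_b.n_clusters + 1):
            set_b = set(assign_b.members(cb))
            j = len(set_a & set_b) / len(set_a | set_b)
            if j > best[0]:
                best = (j, cb)
        if best[1] is None:
            continue
        set_b = set(assign_b.members(best[1]))
        enr = overlap_enrichment(set_a, set_b, universe)
        rows.append(
            {
                "cluster_a": ca,
                "best_cluster_b": best[1],
                "jaccard": best[0],
                "size_a": len(set_a),
                "size_b": len(set_b),
                "k": enr["k"],
                "p_hyper": enr["p_hyper"],
            }
        )
    matches = pd.DataFrame(rows)
    if len(matches):
        _, p_adj, _, _ = multipletests(matches["p_hyper"], method="fdr_bh")
        matches["p_adjusted"] = p_adj

    marker_a = marker_b = None
    venn = (0, 0, 0)
    if markers:
        marker_a = locate_cluster_by_markers(assign_a, markers)
        marker_b = locate_cluster_by_markers(assign_b, markers)
        venn = venn_counts(
            set(assign_a.members(marker_a)), set(assign_b.members(marker_b))
        )

    diff = node_differential(table, grouping)
    return GroupComparison(
        matches=matches,
        marker_cluster_a=marker_a,
        marker_cluster_b=marker_b,
        venn=venn,
        differential=diff,
    )
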