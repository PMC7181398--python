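"""Model/Results facade over the functional-niche pipeline.

:class:`FunctionalNicheModel` is constructed from the two abundance tables
plus animal metadata; :meth:`~FunctionalNicheModel.fit` runs the full
analysis — normalization, the two abundance filters, table merge, Pearson
co-abundance network, MCL clustering, per-cluster PLS/VIP scoring, the
high/low-emitter split with its least-squares-means contrast, and LDA
discrimination on the union of selected variables — and returns a
:class:`NicheAnalysisResults` carrying every intermediate object, a
``summary()`` table, and plotting helpers.

Example
-------
>>> from methaniche import FunctionalNicheModel, paper_scale
>>> model = FunctionalNicheModel.from_synthetic(paper_scale(seed=7))
>>> results = model.fit()
>>> print(results.summary())      # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import diffnet
from .data import (
    AbundanceTable,
    FeatureAnnotation,
    FilterReport,
    SampleMetadata,
    merge_tables,
    normalize_relative,
    filter_min_abundance,
    filter_prevalence,
)
from .discriminate import EmitterGrouping, LdaModel, lda_fit, lsmeans_difference, split_emitters
from .network import (
    ClusterAssignment,
    CoabundanceNetwork,
    build_network,
    cluster_summary,
    mcl_cluster,
    pearson_matrix,
)
from .pls import ClusterPlsReport, run_all_clusters
from .simulate import GroundTruth, SyntheticConfig, generate_dataset, synthetic_annotation

__all__ = ["FunctionalNicheModel", "NicheAnalysisResults"]


class FunctionalNicheModel:
    """Functional-niche co-abundance analysis of a microbiome vs methane yield.

    Parameters
    ----------
    gene_table, genus_table : AbundanceTable
        KO-gene and genus abundance tables over the same animals; counts are
        normalized to percent automatically.
    metadata : SampleMetadata
        Breed, diet and CH4 yield per animal.
    annotation : FeatureAnnotation, optional
        Feature labels/domains for cluster composition reports.
    min_abundance_percent : float
        Gene features at or below this mean relative abundance are dropped.
    max_zero_samples : int
        Features with zeros in more than this many animals are dropped.
    correlation_threshold : float
        Minimum Pearson r for a network edge.
    inflation : float
        MCL inflation (granularity) parameter.
    vip_threshold, max_vars : float, int
        Per-cluster variable-selection rule (VIP > threshold, at most
        ``max_vars`` variables).
    ridge : float
        LDA covariance regularization.
    """

    def __init__(
        self,
        gene_table: AbundanceTable,
        genus_table: AbundanceTable,
        metadata: SampleMetadata,
        annotation: FeatureAnnotation | None = None,
        *,
        min_abundance_percent: float = 0.001,
        max_zero_samples: int = 2,
        correlation_threshold: float = 0.70,
        inflation: float = 2.2,
        vip_threshold: float = 0.8,
        max_vars: int = 5,
        ridge: float = 1e-6,
        ground_truth: GroundTruth | None = None,
    ) -> None:
        self.gene_table = (
            normalize_relative(gene_table) if gene_table.units == "counts" else gene_table
        )
        self.genus_table = (
            normalize_relative(genus_table) if genus_table.units == "counts" else genus_table
        )
        self.metadata = metadata
        self.annotation = annotation
        self.min_abundance_percent = min_abundance_percent
        self.max_zero_samples = max_zero_samples
        self.correlation_threshold = correlation_threshold
        self.inflation = inflation
        self.vip_threshold = vip_threshold
        self.max_vars = max_vars
        self.ridge = ridge
        self.ground_truth = ground_truth

    @classmethod
    def from_synthetic(
        cls, config: SyntheticConfig, seed: int | None = None, **kwargs
    ) -> "FunctionalNicheModel":
        """Build the model on a freshly drawn synthetic dataset."""
        genes, genera, metadata, truth = generate_dataset(config, seed=seed)
        annotation = synthetic_annotation(truth)
        return cls(
            genes, genera, metadata, annotation, ground_truth=truth, **kwargs
        )

    # ------------------------------------------------------------------
    def fit(self) -> "NicheAnalysisResults":
        """Run the full pipeline and return the results object."""
        genes, rep_gene_ab = filter_min_abundance(
            self.gene_table, self.min_abundance_percent
        )
        genes, rep_gene_prev = filter_prevalence(genes, self.max_zero_samples)
        genera, rep_genus_prev = filter_prevalence(
            self.genus_table, self.max_zero_samples
        )
        merged = merge_tables(genes, genera)
        # constant features cannot enter a correlation network
        sd = merged.values.std(axis=1)
        merged = merged.subset_features(merged.values.index[sd > 0])

        corr = pearson_matrix(merged)
        network = build_network(corr, threshold=self.correlation_threshold)
        assignment = mcl_cluster(network, inflation=self.inflation)

        cluster_reports = run_all_clusters(
            assignment,
            merged,
            self.metadata,
            vip_threshold=self.vip_threshold,
            max_vars=self.max_vars,
        )

        grouping = split_emitters(self.metadata)
        contrast = lsmeans_difference(self.metadata, grouping)

        selected_ids = sorted(
            {
                fid
                for r in cluster_reports
                for fid in r.selected["feature_id"]
            }
        )
        lda = None
        if selected_ids:
            x = merged.subset_features(selected_ids).values.T
            lda = lda_fit(x, grouping, ridge=self.ridge)

        composition = (
            cluster_summary(assignment, self.annotation, merged)
            if self.annotation is not None
            else None
        )

        return NicheAnalysisResults(
            model=self,
            merged_table=merged,
            filter_reports=[rep_gene_ab, rep_gene_prev, rep_genus_prev],
            correlation=corr,
            network=network,
            assignment=assignment,
            cluster_reports=cluster_reports,
            composition=composition,
            grouping=grouping,
            group_contrast=contrast,
            lda=lda,
            selected_ids=selected_ids,
        )


@dataclass
class NicheAnalysisResults:
    """Fitted functional-niche analysis: every stage's output plus reports."""

    model: FunctionalNicheModel
    merged_table: AbundanceTable
    filter_reports: list[FilterReport]
    correlation: object
    network: CoabundanceNetwork
    assignment: ClusterAssignment
    cluster_reports: list[ClusterPlsReport]
    composition: pd.DataFrame | None
    grouping: EmitterGrouping
    group_contrast: dict[str, float]
    lda: LdaModel | None
    selected_ids: list[str] = field(default_factory=list)

    # -- tabular views --------------------------------------------------
    def cluster_table(self) -> pd.DataFrame:
        """Per-variable scorecard mirroring the field's reporting tables.

        One row per selected variable: cluster, feature, VIP (from the
        selection model when available), signed regression coefficient from
        the final fixed-effect-free PLS, the cluster's % of CH4 variance
        explained and its direction.
        """
        rows = []
        for r in self.cluster_reports:
            for _, v in r.selected.iterrows():
                rows.append(
                    {
                        "cluster": r.cluster,
                        "feature_id": v["feature_id"],
                        "vip": v.get("selection_vip", v["vip"]),
                        "coefficient": v["coefficient"],
                        "variance_explained_percent": r.variance_explained_percent,
                        "direction": r.direction,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable overview of the fitted analysis."""
        n_pos = sum(1 for r in self.cluster_reports if r.direction == "positive")
        n_neg = sum(1 for r in self.cluster_reports if r.direction == "negative")
        lines = [
            "Functional-niche co-abundance analysis",
            "=" * 54,
            f"samples:                {self.merged_table.n_samples}",
            f"features after filters: {self.merged_table.n_features}",
            f"network nodes / edges:  {self.network.n_nodes} / {self.network.n_edges}"
            f"  (threshold r >= {self.network.threshold})",
            f"dropped (uncorrelated): {len(self.network.dropped_nodes)}",
            f"MCL clusters:           {self.assignment.n_clusters}"
            f"  (inflation {self.model.inflation})",
            f"emitter split:          LME {self.grouping.sizes.get('LME', 0)}"
            f" / HME {self.grouping.sizes.get('HME', 0)}",
            (
                "HME-LME contrast:       "
                f"{self.group_contrast['estimate']:.2f} g/kg DMI "
                f"(SE {self.group_contrast['se']:.2f}, p={self.group_contrast['p']:.2g})"
            ),
            f"clusters associated:    {n_pos} positive, {n_neg} negative",
        ]
        if self.lda is not None:
            lines.append(
                "LDA accuracy:           "
                f"resubstitution {self.lda.resubstitution_accuracy:.2f}, "
                f"leave-one-out {self.lda.loo_accuracy:.2f} "
                f"({len(self.selected_ids)} variables)"
            )
        lines.append("")
        lines.append("Top clusters by % CH4 variance explained:")
        for r in self.cluster_reports[:10]:
            lines.append(
                f"  cluster {r.cluster:>3}: {r.variance_explained_percent:5.1f}% "
                f"({r.direction or 'n/a'}, {len(r.selected)} variables)"
            )
        return "\n".join(lines)

    # -- downstream analyses -------------------------------------------
    def compare_emitter_networks(
        self, markers: list[str] | None = None
    ) -> diffnet.GroupComparison:
        """Separate HME/LME networks, matched clusters, marker-cluster Venn."""
        return diffnet.compare_group_networks(
            self.merged_table,
            self.model.metadata,
            self.grouping,
            markers=markers,
            threshold=self.model.correlation_threshold,
            inflation=self.model.inflation,
        )

    def recovery_scores(self) -> dict[str, float] | None:
        """Agreement with planted structure, when ground truth is known.

        Returns the adjusted Rand index between the MCL clustering and the
        planted block membership over network nodes belonging to planted
        blocks, or None without ground truth.
        """
        truth = self.model.ground_truth
        if truth is None:
            return None
        from .compositional import adjusted_rand_index

        planted = truth.membership[truth.membership > 0]
        shared = self.assignment.labels.index.intersection(planted.index)
        if len(shared) == 0:
            return None
        ari = adjusted_rand_index(self.assignment.labels.loc[shared], planted.loc[shared])
        return {"ari_vs_planted_blocks": ari, "n_scored_nodes": len(shared)}

    # -- plots ----------------------------------------------------------
    def plot_cluster_variance(self, ax=None):
        """Bar chart of % CH4 variance explained per cluster."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        reports = [r for r in self.cluster_reports if len(r.selected)]
        labels = [f"c{r.cluster}" for r in reports]
        vals = [r.variance_explained_percent for r in reports]
        colors = ["tab:red" if r.direction == "positive" else "tab:blue" for r in reports]
        ax.bar(labels, vals, color=colors)
        ax.set_ylabel("% CH4 variance explained")
        ax.set_xlabel("cluster")
        return ax

    def plot_discriminant_scores(self, ax=None):
        """Density of LDA scores by emitter group."""
        import matplotlib.pyplot as plt

        if self.lda is None:
            raise ValueError("no LDA model fitted (no variables selected)")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        data = self.lda.density_data(self.grouping)
        for group, color in (("LME", "tab:blue"), ("HME", "tab:red")):
            ax.hist(
                data.loc[data["group"] == group, "score"],
                bins=15,
                alpha=0.5,
                density=True,
                label=group,
                color=color,
            )
        ax.axvline(self.lda.threshold, ls="--", color="k", lw=0.8)
        ax.set_xlabel("discriminant score")
        ax.legend()
        return ax
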