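# Methods

This note documents the models and procedures implemented in `methaniche`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show
about real rumen metagenomics data.

## Data model and filtering

Abundance tables are features × animals with a per-feature kind tag (KO
gene or genus) and a units tag (raw counts or percent). Normalization
closes each animal's column to 100% *separately within each kind* — genes
and genera come from different quantification routes and are normalized
independently before being stacked. On merge, feature ids are namespaced
(`gene:K00399`, `genus:Methanobrevibacter`) so the joint feature space
cannot collide. Filtered tables keep surviving values untouched (filters
only drop rows), so exact closure is guaranteed only at normalization time;
the container invariant enforced afterwards is that no kind's column sum
exceeds 100.

Two filters precede network analysis, both with the boundary semantics
tested explicitly:

* **prevalence** — a feature with zero abundance in *more than* 2 animals
  (i.e. 3 or more of 63) is removed;
* **minimum abundance** — a gene feature whose abundance does not *strictly
  exceed* 0.001% is removed. The rule is applied to the **mean** relative
  abundance across animals (a per-animal variant is available via
  `per_sample=True`): a per-animal rule would interact with the separate
  prevalence filter and make survival depend on sample order.

## Co-abundance network and MCL

Edges are Pearson correlations r ≥ 0.70 between percent-abundance
profiles; negative correlations never form edges, and the boundary is
inclusive by default (`inclusive=False` gives strict >). Features with no
retained edge are reported as dropped rather than entering the graph as
isolates.

The Markov Cluster algorithm is implemented from scratch on sparse
matrices: add a self-loop of weight 1 per node (standard regularization,
prevents bipartite oscillation), column-normalize, then iterate
**expansion** (matrix power, default 2), **inflation** (entry-wise power,
default 2.2, followed by column renormalization) and **pruning** of entries
below 1e-5 (renormalizing again) until the matrix changes by less than 1e-8
or 200 iterations (non-convergence emits a warning and uses the last
iterate). Clusters are read off the limit matrix as connected components of
its attractor structure: rows retaining diagonal mass are attractors, and
every column joins the attractors serving it. The result is a partition,
deterministic given node order, with clusters numbered 1, 2, … by
decreasing size (so "cluster 1" is always the largest). Inflation 2.2
follows the convention of the graph-analysis tools this pipeline emulates;
granularity is the user's knob (`--inflation`). The test suite checks
partition-for-partition equivalence against an independently written dense
reference implementation on randomized block graphs, column-stochasticity
after every normalization, and the impossibility of clusters spanning
disconnected components.

## SparCC compositional check

Closure makes naive Pearson correlations on relative abundances biased
negative. The SparCC estimator infers *basis* (underlying absolute
abundance) correlations from the variation matrix t_ij = Var(log x_i − log
x_j) under a sparsity assumption, solving Σ_{j≠i} t_ij = (p−2)ω_i + Σ_j ω_j
for the basis variances ω and then ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_i ω_j)),
clipped to [−1, 1]. Up to 10 strongly correlated pairs (|ρ| > 0.1) are
excluded from the system one at a time and the variances re-solved.
Choices:

* **Deterministic pseudocount** (1e-6 on the percent scale; use ~0.5 on raw
  counts) instead of the original Dirichlet resampling of zeros — a
  deliberate deviation in favour of reproducibility, since the estimator is
  used here as a structural robustness check, not for inference. No
  bootstrap p-values for the same reason.
* The estimator works on per-animal **fractions** (columns divided by their
  totals before the pseudocount), which makes it exactly invariant to
  rescaling any animal's column.
* Nonpositive basis-variance estimates are floored at half the smallest
  positive t_ij with a warning.
* The 3-feature system is exactly solvable and available under
  `relaxed=True` (exclusion disabled); the default requires ≥ 4 features.

The clustering built on SparCC correlations is compared with the
Pearson-based one by adjusted Rand index (implemented from the pair-counting
contingency formula, cross-checked in tests against brute-force pair
enumeration and scikit-learn) over the nodes present in both networks, plus
per-cluster best-match Jaccard. The robustness bar used in the acceptance
run — ARI ≥ 0.7 on study-scale synthetic data — is this package's own
operationalization of "similar clustering"; no quantitative standard exists
for it. On study-scale synthetic data the observed agreement is ~0.97:
background features swept into spurious Pearson clusters by closure mostly
drop out of the SparCC network entirely rather than scrambling shared
clusters.

## Per-cluster PLS and VIP selection

The PLS engine is NIPALS PLS1: center (and autoscale, by default) X and y;
per component w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflate,
repeat. Coefficients are mapped back to the original predictor scale, and
`variance_explained` is the in-sample R² of the one-component fit — a
descriptive quantity, deliberately not cross-validated. VIP_j =
√(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a) satisfies Σ VIP² = p; for one
component it reduces to √p·|w_j|. One latent component is used everywhere,
selection and final fit alike, keeping the two fits commensurable.

"Fixed effects inside a PLS" has no native meaning, so diet and breed enter
the **selection** fit as binary dummy predictors appended to X but barred
from being selected; an alternative (`residualize_fixed_effects=True`)
regresses them out of y first. The selection keeps at most 5 features with
VIP strictly above 0.8, ties broken by |coefficient| then feature id — the
mechanical rule only; no expert-knowledge override is implemented. The
**final** fit per cluster uses the selected features alone, without
dummies, and reports % variance explained and a direction (sign consensus
of the coefficients, ties decided by their sum). Clusters whose features
all fall below the VIP threshold are reported as non-informative at 0%.

## Emitter grouping, contrast, and LDA

The high/low emitter split is a median split of g CH4/kg DMI — the
floor(n/2) lowest animals are LME (31 of 63), ties broken by animal id. The
underlying study's exact grouping rule is not recoverable from its outcome
alone; a median split is the simplest rule reproducing a 31/32 partition.

The group contrast is OLS with additive group + breed + diet dummies; in an
additive model the difference of least-squares means (equal weights over
breed × diet cells) equals the group coefficient, reported with its SE and
two-sided t-test p-value. A rank check rejects designs where the group is
confounded with the other factors. Type-I error is verified at 5% ± 2% by
null permutation in the test suite.

Two-class Fisher LDA uses the pooled within-class covariance regularized as
S + ridge·trace(S)/p·I (default ridge 1e-6) — necessary because the number
of selected variables can approach the number of animals — with a decision
threshold from the class-mean midpoint and empirical log prior odds. Both
resubstitution and leave-one-out accuracy are always reported together:
with ~50 predictors on 63 animals, resubstitution accuracy reaches 100%
even for pure noise, and a reader seeing only that figure would be misled.
On study-scale synthetic data the pipeline reproduces exactly this pattern
(resubstitution 1.00, leave-one-out ≈ 0.5 when selected variables carry
mostly compositional echo of the drivers).

## Differential networks

The pooled pipeline is re-run on the HME and LME sample subsets separately
(features constant within a subset are excluded from that subset's network
only). Clusters are matched across networks by maximum Jaccard (greedy,
ties to the smaller id); each matched pair gets an upper-tail
hypergeometric overlap probability — drawing |A| nodes from the union
universe with |B| successes, P(X ≥ k) — with Benjamini–Hochberg adjustment
across pairs. The enrichment machinery of the original graph tool is
undocumented; the hypergeometric test is this package's explicit stand-in,
and both node-membership overlap and per-feature abundance differences
(Welch t-tests, flagged at unadjusted P < 0.05 with BH-adjusted values
alongside) are reported so either reading of "enrichment" is available. A
marker list (e.g. the dominant methanogens) locates the marker cluster in
each network by plurality, and its two node sets are reduced to a Venn
triple (shared, only-HME, only-LME).

## Synthetic data generator

Per animal j and block k: factor f_kj ~ N(0,1); member feature i has
log-abundance L_ij = μ_i + λ_i f_kj + ε_ij with ε ~ N(0, σ²); columns are
soft-maxed to compositions within each feature kind, sampled as
multinomial counts at a fixed depth (inducing realistic zeros), and closed
to percent. Methane yield is β0 + Σ_k γ_k f_kj + δ·1[FOR] +
breed·1[AA] + η, η ~ N(0, τ²). Diet and breed follow a cycled, near-balanced
2×2 layout. The fraction of response variance planted in block k —
γ_k²/(Σγ² + δ²Var(diet) + breed²Var(breed) + τ²) — is available in closed
form (`planted_r2`) for recovery scoring. Everything drawn is recorded in a
`GroundTruth`.

Default conditions (`paper_scale`): 63 animals; 1,557 gene + 1,160 genus
features (2,717 merged); ten blocks totalling ~1,600 features, the largest
with 329 genes + 98 genera; three driver blocks planted at variance
fractions 0.40/0.20/0.05; baseline log-means uniform on [−4, 2] (a ~400-fold
abundance dynamic range); sequencing depth 3×10⁵ per kind (deep enough for
stable correlations, shallow enough that low-abundance features still hit
the prevalence filter); β0 = 17.56 g/kg DMI with γ/τ split so the total CH4
CV is 12.5%; diet effect 2.0 g/kg DMI and breed effect 0.5 (breed effects
on methane yield are typically small and non-significant at this sample
size).

Two generator parameters deserve explanation:

* **Loading scale.** Percent-scale abundance is *exponential* in the block
  factor, so a feature's linear correlation with the factor is
  λ/√(e^{λ²+σ²}−1): large loadings produce heavily skewed features that are
  poor linear proxies of the factor even though their mutual correlations
  stay high. Block loadings therefore default to U(0.4, 0.6) with log-noise
  σ = 0.15 — the near-linear regime, giving within-block correlations
  ~0.9 while keeping the planted variance fraction linearly recoverable.
  Strong-loading scenarios (λ ∈ [1.5, 2]) remain available per block and
  are exercised in the tests for the network-formation properties.
* **Condition-specific expansion.** A block can carry extra features whose
  loading is active only in animals whose block factor is below its median
  (`n_low_expansion_*`). Since the factor raises methane yield, those
  animals are predominantly low emitters, so the expansion joins the
  cluster in the LME network only — the mechanism behind the dual-network
  comparison scenario.

What the generator does **not** emulate: phylogenetic correlation between
taxa, gene-to-genome linkage (a genome's genes co-varying as a unit beyond
the planted blocks), diet-dependent abundance shifts (diet affects only the
response, not the microbiome), overdispersion beyond multinomial, and batch
or chamber effects. Passing recovery tests therefore show the *pipeline's
statistics* behave as designed under compositional closure and sampling
zeros — not that the biological conclusions of any particular real-data
analysis are correct.

## Numerical choices and degenerate inputs

* Correlation matrices are symmetrized and clipped to [−1, 1]; constant
  features are an error at the correlation stage and are removed upstream
  by the pipeline facade.
* MCL: pruning threshold 1e-5, convergence 1e-8 on the max entry change;
  degenerate limit states with no attractor fall back to argmax columns.
* PLS: constant predictors and zero-variance responses are errors; the
  reported R² is clipped to [0, 1].
* LDA with fewer than 2 animals per class is an error; leave-one-out folds
  that would drop a class below 2 are skipped (scored as incorrect).
* Welch tests on features constant in both groups return p = 1, unflagged.
* All stochastic components take an explicit seed; identical seeds give
  byte-identical outputs.

## Problem sizes used in the reproduction runs

The acceptance script runs the full pipeline at the study scale (63
animals, 2,717 features) for one seed, parameter recovery over 8 seeds,
driver recall over 10 seeds, and 500 null replicates for the contrast
calibration. The test suite's recovery check uses 50 seeds at full scale
and 1,000 null replicates, the sizes at which the planted-versus-recovered
comparisons were designed to stabilize.

## Known limitations

* The exact cluster count of any particular real dataset depends on the
  (undisclosed) inflation of the original analysis tool; no attempt is made
  to reproduce a specific cluster count, only the structural behaviour.
* VIP selection implements the mechanical threshold rule; published
  analyses sometimes override it with biological-knowledge exceptions,
  which a pipeline cannot and should not reproduce.
* In-sample variance explained from selected-then-refit variables carries
  winner's-curse optimism of a few percentage points for weakly planted
  blocks; the recovery tests quantify it rather than correcting it.
* The SparCC implementation estimates point correlations only; no
  significance machinery.
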