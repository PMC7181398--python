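# methaniche

Functional-niche analysis of the rumen microbiome and its association with
methane emissions.

Ruminants emit methane as an end product of anaerobic microbial
fermentation, and the amount emitted per kilogram of dry-matter intake
(g CH4/kg DMI) varies substantially between animals. Much of that variation
traces back not to the methanogenic archaea alone but to the wider web of
microbial interactions that supply (or divert) methanogenesis substrates.
`methaniche` implements, as a tested and reusable pipeline, the
co-abundance network approach to this question: microbial **genera** and
**KEGG-ortholog (KO) genes** quantified as relative abundances across
animals are linked into a network wherever their abundance profiles
correlate, the network is partitioned into clusters interpreted as
*functional niches*, and each niche is scored for how much of the methane
variation it explains.

## The method

Given a gene table and a genus table (features × animals), per-animal
metadata (breed ∈ {AA, LIM}, diet ∈ {FOR, CONC}, CH4 in g/kg DMI), the
pipeline is:

1. **Normalize and filter.** Abundances are closed to 100% per animal
   within each feature kind. Gene features with mean relative abundance
   ≤ 0.001% are removed, and any feature with zero counts in 3 or more
   animals is removed (sparse rows destabilize co-abundance estimates).
2. **Co-abundance network.** Pearson correlation r between every feature
   pair; an undirected edge is kept where r ≥ 0.70 (positive correlations
   only). Features correlated with nothing are dropped from the network.
3. **MCL clustering.** The Markov Cluster algorithm — alternating
   *expansion* (matrix squaring, simulating flow) and *inflation*
   (entry-wise power 2.2 with column renormalization, sharpening flow) on
   the column-stochastic adjacency — partitions the network into clusters.
4. **Per-cluster PLS/VIP scoring.** For each cluster, a one-component PLS
   of CH4 on the cluster's features plus diet/breed dummies ranks features
   by VIP (variable importance for projection; Σ VIP² = p). At most 5
   features with VIP > 0.8 are kept, and a final PLS without fixed effects
   reports the cluster's % of CH4 variance explained with signed
   coefficients.
5. **Emitter discrimination.** Animals are split at the median into low
   (LME) and high (HME) emitters; the group contrast is estimated by OLS
   least-squares means (group + breed + diet), and Fisher LDA on the
   selected variables reports both resubstitution and leave-one-out
   accuracy (the former is wildly optimistic with ~50 predictors on 63
   animals, and the package says so).
6. **Robustness and group comparison.** Because relative abundances are
   compositional (closure induces spurious negative correlation), the
   clustering is cross-checked against a from-scratch SparCC
   basis-correlation estimate; and separate HME/LME networks are compared
   cluster-by-cluster (Jaccard matching, hypergeometric overlap enrichment,
   Venn decomposition of the marker cluster, per-feature Welch tests).

A fully ground-truthed synthetic generator (`methaniche.simulate`) emulates
the processed data layer — compositional closure, multinomial sequencing
zeros, block co-abundance structure, and a response driven by a subset of
blocks plus diet/breed effects — so every stage can be scored against what
was planted.

## Worked example

```python
import methaniche as m

model = m.FunctionalNicheModel.from_synthetic(m.paper_scale(seed=7))
results = model.fit()
print(results.summary())
```

prints

```
Functional-niche co-abundance analysis
======================================================
samples:                63
features after filters: 2604
network nodes / edges:  1430 / 88142  (threshold r >= 0.7)
dropped (uncorrelated): 1174
MCL clusters:           48  (inflation 2.2)
emitter split:          LME 31 / HME 32
HME-LME contrast:       2.53 g/kg DMI (SE 0.30, p=6.1e-12)
clusters associated:    10 positive, 9 negative
LDA accuracy:           resubstitution 1.00, leave-one-out 0.49 (59 variables)

Top clusters by % CH4 variance explained:
  cluster   2:  32.5% (positive, 5 variables)
  cluster   1:  20.8% (positive, 5 variables)
  ...
```

Reading this: of 2,717 simulated features, 2,604 survive the abundance and
prevalence filters and 1,430 correlate with at least one other feature at
r ≥ 0.70; MCL finds 48 clusters. High emitters average 2.53 g CH4/kg DMI
more than low emitters after adjusting for breed and diet. The top clusters
correspond to the planted response-driving blocks
(`results.recovery_scores()` reports an adjusted Rand index of 0.96 between
clusters and planted blocks at this seed). The perfect resubstitution
accuracy next to chance-level leave-one-out accuracy is the expected
overfitting exhibit for ~59 predictors on 63 animals. Per-variable detail
in the style of a per-cluster scorecard (VIP, regression coefficient, %
explained, direction) comes from `results.cluster_table()`.

The same stages are scriptable from a shell:

```bash
methaniche simulate --seed 4 --out sim/
methaniche network --genes sim/genes.tsv --genera sim/genera.tsv --out edges.tsv
methaniche cluster --edges edges.tsv --out clusters.tsv
methaniche pls --genes sim/genes.tsv --genera sim/genera.tsv \
    --metadata sim/metadata.csv --clusters clusters.tsv --out scorecard.tsv
methaniche group-contrast --metadata sim/metadata.csv
```

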