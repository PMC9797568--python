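# stressweave

Multi-omics network analysis of microbial stress responses, built around
the workflow used to characterize how an industrial *Saccharomyces
cerevisiae* strain tolerates the lignocellulosic inhibitor *p*-coumaric
acid: chemostat physiology, attribute-enhanced protein–protein
interaction (PPI) clustering, hub-gene detection, Bayesian
gene–phenotype association, short-variant profiling, and assembly of a
signed multi-omics integration network.

It is a library first (import `stressweave`, see `examples/`), with a thin
`stressweave` CLI for running stages or the whole pipeline from the shell.

## What it computes

**Chemostat physiology.** At steady state the specific rate of a compound
follows the mass balance *q* = ±1000·*D*·(*c*_feed − *c*_residual)/(MW·*X*)
(mmol gDW⁻¹ h⁻¹, consumption negative), yields are
*Y*_X/S = *X*/Δ*S* and *Y*_Eth/S = *c*_EtOH/Δ*S*, and conditions are
compared by percent change 100·(treated − control)/control and
log₂(treated/control).

**Attribute-enhanced clustering.** High-confidence interactions
(ppi_score ≥ 0.7) between differentially expressed genes are re-weighted
by regulation similarity,

    foldChange_score(i, j) = 1 − |Xᵢ − Xⱼ| / max_distance

with *Xᵢ* the gene's log₂ fold change and *max_distance* the largest
pairwise gap on retained edges, then combined multiplicatively into an
`enhanced_score` ∈ [0, 1]. Markov clustering (MCL: alternating matrix
expansion and entrywise inflation of a column-stochastic flow matrix) is
run on these weights with the inflation *r* tuned to maximize weighted
Newman modularity *Q*. Clusters with > 20 genes whose whisker-trimmed
(1.5 × IQR) fold changes share one sign are selected; each member is
ranked by degree, betweenness, closeness and eigenvector centrality on
its cluster's induced subgraph, and genes in the top-3 of ≥ 3 metrics are
called local hubs. Functional labels come from hypergeometric
over-representation with Benjamini–Hochberg FDR.

**Gene–phenotype association.** Per-sample expression and phenotypes are
discretized with Sturges' rule (*k* = ⌈1 + log₂ *n*⌉, equal-width bins);
each gene→phenotype link is scored by the Dirichlet–multinomial evidence
gain of conditioning the phenotype classes on the gene classes, signed by
the Pearson correlation of the raw values.

**Variants.** Diploid genotypes are classified as homozygous,
heterozygous-with-reference, or heterozygous-without-reference; VEP-style
consequence terms map to MODIFIER/LOW/MODERATE/HIGH impact tiers.

**Integration.** A directed typed network (variant → gene →
pathway/phenotype) with weights in {−1, 0, +1}: +1 where gene regulation
moves with the linked pathway/phenotype change, −1 where it opposes it,
0 for variant links. The reported model keeps edges touching hub or
flagged genes.

A synthetic-data module generates every input with planted structure
(community memberships, association signs, variant classes) so recovery
can be measured exactly.

## Worked example

```bash
python examples/02_cluster_enhanced_network.py
```

prints

```
enhanced graph: 120 genes, 563 edges
tuned inflation r = 1.4, modularity Q = 0.748
clusters found = 4, adjusted Rand index vs planted = 1.00
...
cluster 0: 30 genes, median log2FC +2.03 (up)
cluster 1: 30 genes, median log2FC -1.98 (down)
```

The planted four-community network (30 genes each, intra-cluster edge
probability 0.3, inter 0.01, fold-change centres ±2/±1.5) is recovered
exactly: ARI 1.0 against the ground truth, with two up- and two
down-regulated clusters. The other examples cover physiology
(`q_ethanol +53 %`, `Y_EthS +21 %` between control and stressed
chemostats), phenotype association (60/60 planted signs recovered),
variant profiling, and the integrated model (11 anchored genes, 18
positive / 12 negative interactions on the default synthetic run).

The same pipeline runs from the shell:

```bash
stressweave simulate --out sim --seed 7          # write synthetic inputs
stressweave run --config config.yaml             # full pipeline + report
```

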