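# Methods

This note documents the models, defaults and numerical choices behind
each stage of the pipeline, what the synthetic generator does and does
not emulate, and the known limitations.

## Chemostat physiology

At steady state in a chemostat the growth rate equals the dilution rate
*D*, so a compound's specific rate follows from a mass balance over the
vessel: *q* = ±1000·*D*·(*c*_feed − *c*_residual)/(MW·*X*), in
mmol gDW⁻¹ h⁻¹ with consumption negative. Molar masses for glucose
(180.16), ethanol (46.07), glycerol (92.09), CO₂ (44.01) and the minor
organic acids are built in and overridable, since concentrations arrive
in g/L but rates are reported molar. Yields are ratios of formed product
(biomass or ethanol, g) to consumed glucose (g). Condition comparisons
report percent change relative to the control and log₂ fold change;
percent changes are rounded to integers only in the report layer, and
the two quantities satisfy log₂(1 + pct/100) = log₂FC for positive
inputs (a tested identity). For signed rates the log₂ change is computed
on magnitudes. Carbon recovery is accepted as an input column, not
recomputed — that would need an elemental biomass composition the input
table does not carry. Note that comparisons derived from a *rounded*
measurement table can differ by a point from values computed on raw
replicate data (e.g. glucose uptake: 26.55 % → 27 from the rounded
entries).

## Attribute-enhanced graph

Only interactions at or above the confidence threshold (default 0.7 on
the [0,1] scale; 0–1000 integer scores are rescaled automatically) and
between genes with fold-change records are kept. Genes without fold
changes are dropped with a warning rather than imputed at zero —
imputation would invent co-regulation signal. Each retained edge gets

* `fold_change_score` = 1 − |Xᵢ − Xⱼ|/max_distance, where max_distance
  is taken over retained edges by default (`normalize_over="pairs"`
  switches to all node pairs); the score is 1 for identically regulated
  genes and 0 for the most dissimilar connected pair, and is invariant
  under shifting all fold changes by a constant;
* `enhanced_score` = fold_change_score × ppi_score (default) or their
  arithmetic mean. The product is used because it stays in [0,1], is
  monotone in both inputs, and zeroes out maximally dissimilar pairs, so
  flow in the clustering step cannot cross regulation boundaries through
  a single high-confidence edge.

DEG filtering defaults to FDR ≤ 0.01 and |log₂FC| ≥ 0.5; an optional raw
p-value cap and a higher fold-change floor express the stricter variant
(p < 0.05, |log₂FC| ≥ 1) used when a smaller gene set is wanted.

## Markov clustering and cluster selection

MCL is implemented directly on a dense column-stochastic matrix:
self-loops with weight equal to the node's maximum incident weight
(1 for isolated nodes) stabilize attractors; each iteration squares the
matrix (expansion), raises entries to the inflation power *r* and
renormalizes (inflation), and prunes entries below 1e−5 — never a
column's maximum, so columns stay stochastic to 1e−9 (asserted every
step). Iteration stops when the matrix changes by less than 1e−8 in max
norm, or after 200 iterations with a best-effort partition flagged
non-converged. Clusters are read from the limit matrix: nodes with
positive diagonal are attractors, attractors that attract one another
form one attractor system, and every other node joins the system that
attracts it. A node attracted by several systems goes to the larger one,
then to the one with the lexicographically smallest member — a pure
tie-break for determinism. Dense algebra is deliberate: the graphs this
package targets (DEG-restricted PPI subnetworks, a few hundred nodes)
never justify sparse machinery.

Modularity is weighted Newman *Q* on the enhanced scores with self-loops
excluded, delegated to networkx and cross-checked in the tests against an
independent pairwise-sum oracle; an empty edge set is defined as *Q* = 0
with a warning. Inflation is tuned over a grid (default 1.2–5.0 in steps
of 0.2) by maximizing *Q*, ties toward the smaller, coarser inflation.
Both the partition and *Q* are invariant under positive rescaling of the
weights and under node relabeling, which the tests assert.

Cluster selection keeps clusters with more than 20 genes whose
fold-change distribution, after removing values outside the 1.5 × IQR
whiskers, lies strictly on one side of zero. Whisker outliers do not veto
the direction label and remain cluster members: the filter describes the
distribution, it does not edit membership.

## Hubs and enrichment

Centralities (degree, betweenness as raw shortest-path pair counts,
closeness as (n−1)/Σd within the node's component, eigenvector
max-normalized per cluster) are computed on each cluster's induced
subgraph, unweighted by default; a flag enables weighted variants with
distance = 1/enhanced_score. The unweighted default avoids committing to
a weight-to-distance convention where none is canonical. A gene is a
local hub when it ranks in the top 3 of at least 3 of the four metrics
within its cluster (ordinal ranks, ties by gene id). The rule is a
declared heuristic chosen to yield a handful of hubs on clusters of
20–80 genes; both knobs are exposed. Singleton clusters score 0 on all
metrics.

Enrichment is the hypergeometric upper tail of a term's overlap with the
cluster against the supplied gene universe, with fold enrichment =
observed/expected overlap and BH FDR applied across terms within each
cluster. A cluster's label is the lowest-FDR term with FDR ≤ 0.01 that
covers at least 50 % of the cluster, ties toward larger coverage.

## Gene–phenotype association

Observations are discretized with Sturges' rule, *k* = ⌈1 + log₂ n⌉,
equal-width bins over the observed range (constant vectors collapse to
one class; labels are invariant under positive affine transforms). The
association score for a gene→phenotype link is the difference in
Dirichlet–multinomial log marginal likelihood of the phenotype classes
conditioned on the gene classes versus unconditioned, with a BDeu-style
prior that splits an equivalent sample size (default 1.0) uniformly over
cells. A link passes when the evidence gain exceeds 0 — conditioning must
pay for its extra parameters, which keeps the independent-noise pass rate
near zero at n = 50 — and its sign is the sign of the Pearson correlation
on the undiscretized values, which avoids the sign ambiguity of coarse
class tables. This scores each edge independently; it performs no network
structure search and makes no causal claim. Zero-variance inputs yield a
flagged non-association.

## Variants

Zygosity is classified from diploid genotype strings ("a/b" or "a|b";
phasing ignored, ploidy ≠ 2 rejected): equal non-zero alleles are
homozygous, one reference allele is heterozygous-with-reference, two
distinct variant alleles heterozygous-without-reference; "0/0" and "./."
carry no variant. Consequence terms follow the standard effect-predictor
vocabulary (frameshift/stop-gain/splice-donor → HIGH, missense and
in-frame indels → MODERATE, synonymous and splice-region → LOW,
intron/UTR/up-downstream → MODIFIER); splice_region_variant stays LOW per
that convention even though splice-site classes are sometimes reported
high-impact. When one (variant, gene) pair carries several terms the most
severe tier wins. Summaries report distinct variants separately from
(variant, gene) rows, which can be more numerous because one variant may
be annotated to several genes.

## Integration network

Nodes are typed (variant, gene, pathway, phenotype); edges follow
variant → gene → pathway/phenotype. Gene→pathway edges exist for genes in
pathways passing the perturbation FDR cutoff (default 0.01) and carry +1
when the gene's fold-change direction matches the pathway's perturbation
direction, −1 otherwise; genes with exactly zero fold change are skipped
with a warning. Gene→phenotype edges come from passing associations and
carry the association sign; the phenotype's physiological change
direction (e.g. ethanol rate up, biomass yield down) is supplied
explicitly from the physiology comparison and stored as a node attribute
rather than inferred. Variant→gene edges carry weight 0 and are created
only for MODERATE/HIGH variants. Fermentation/ethanol and ROS/redox
memberships are gene-node flags, not nodes, keeping the graph
layered. Dangling references are collected in a rejects list, not fatal.
The reported model keeps every edge with at least one endpoint in the
anchor set (hub genes plus flagged genes); the extraction is idempotent.

## Synthetic data

The generator plants the structure each stage is supposed to find: a
planted-partition graph (default 4 clusters × 30 genes, p_in = 0.3,
p_out = 0.01) whose intra-cluster confidence range (0.75–0.99) lies above
the 0.7 filter and inter-cluster range (0.40–0.65) below it, so the
high-confidence subgraph is cleanly modular and p_in − p_out acts as a
difficulty dial; per-gene log₂ fold changes centred at ±2 and ±1.5 with
SD 0.3 (two up-, two down-regulated communities); a balanced
two-condition design of 50 samples with expression = baseline (8.0 log₂
units) + condition·log₂FC + noise; phenotypes qEthanol (effect +1 on
cluster 0) and biomass_yield (effect −1 on cluster 1) with noise SD 0.1,
mirroring the ethanol-up/biomass-down physiology; 500 variants drawn
uniformly over the 3 × 4 zygosity × tier grid, 10 % annotated to two
genes. Edge existence and confidence score are sampled independently, and
the expression matrix is generated directly on the log₂ scale — no count
model — because the differential-expression fit happens upstream of this
package. Where the driving study reports no value (phenotype effect
sizes, variant class balance), the defaults are free parameters of the
generator, not estimates of that study. All sub-generators derive their
streams from the single spec seed.

What passing on this data shows — and does not. The generator produces
clean block structure, independent edges, Gaussian noise and balanced
designs. Real PPI networks are hub-heavy and transitive, real expression
has correlated library effects and only a handful of chemostat samples,
and real variant calls cluster along haplotypes. Recovery here therefore
validates the machinery (scores, flow simulation, evidence comparison,
classification rules), not performance guarantees on field data.

## Problem sizes and determinism

Default analyses run on the 120-gene planted network, 50 samples, 500
(or 1000 for calibration) variants, and a 20-point inflation grid —
sizes at which every stage completes in seconds while leaving the
planted-recovery questions non-trivial. All randomness flows from one
integer seed; run reports are reproducible apart from wall-clock
timings.

## Known limitations

* MCL uses dense matrices; graphs beyond a few thousand nodes would need
  a sparse implementation.
* The association stand-in scores one edge at a time; it cannot express
  multi-parent dependencies or dynamics.
* Enrichment treats terms as flat sets: no ontology propagation or
  term-redundancy reduction.
* The integration layer emits all significant pathway memberships for a
  gene; it does not pick a single representative pathway.
* Percent changes computed from rounded input tables can differ by ±1
  point from values derived from raw replicates.
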