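"""Synthetic multi-omics inputs with planted structure.

Every downstream stage of the pipeline is exercised on data generated
here: a planted-partition interaction graph whose communities stand in
for co-expressed gene clusters (intra-cluster edges at probability p_in
with high confidence scores, inter-cluster edges at p_out with scores
below the 0.7 confidence filter), per-gene log2 fold changes centred on
signed cluster means, a balanced two-condition expression matrix,
phenotypes driven linearly by the mean expression of a designated driver
cluster, term memberships that over-represent each planted cluster, and
short variants spanning all zygosity and impact classes. The planted
assignments are returned as a :class:`GroundTruth` so recovery can be
scored (e.g. by adjusted Rand index).

All generators are deterministic for a fixed ``spec.seed``; sub-stage
streams are derived from the one seed so the whole fixture reproduces
from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .variants import TIERS, ZYGOSITY_CLASSES

#: representative VEP-style consequence terms per impact tier
_TIER_TERMS = {
    "MODIFIER": ("intron_variant", "5_prime_UTR_variant", "downstream_gene_variant"),
    "LOW": ("synonymous_variant", "splice_region_variant"),
    "MODERATE": ("missense_variant", "inframe_deletion"),
    "HIGH": ("frameshift_variant", "stop_gained", "splice_donor_variant"),
}
_ZYG_GT = {"homozygous": "1/1", "het_with_ref": "0/1", "het_without_ref": "1/2"}

_EXPRESSION_BASELINE = 8.0  # log2 units, typical mid-range transcript


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Defaults realize a four-community graph of 30 genes each with two up-
    and two down-regulated clusters (fold-change centres +/-2 and
    +/-1.5), a clean separation between the intra-cluster confidence
    range and the 0.7 high-confidence cutoff, a balanced 50-sample
    two-condition design, and one positively driven (qEthanol, effect +1)
    and one negatively driven (biomass yield, effect -1) phenotype with
    noise SD 0.1 — mirroring the ethanol-up / biomass-down physiology the
    pipeline is meant to resolve.
    """

    n_clusters: int = 4
    cluster_sizes: tuple[int, ...] = (30, 30, 30, 30)
    p_in: float = 0.3
    p_out: float = 0.01
    ppi_in_range: tuple[float, float] = (0.75, 0.99)
    ppi_out_range: tuple[float, float] = (0.40, 0.65)
    cluster_fc_means: tuple[float, ...] = (2.0, -2.0, 1.5, -1.5)
    fc_noise_sd: float = 0.3
    n_samples: int = 50
    phenotype_effects: dict[int, tuple[str, float]] = field(
        default_factory=lambda: {0: ("qEthanol", 1.0), 1: ("biomass_yield", -1.0)}
    )
    pheno_noise_sd: float = 0.1
    n_variants: int = 500
    variant_class_probs: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            (z, t): 1.0 / 12.0 for z in ZYGOSITY_CLASSES for t in TIERS
        }
    )
    multi_gene_prob: float = 0.1
    seed: int = 7

    def __post_init__(self) -> None:
        if len(self.cluster_sizes) != self.n_clusters:
            raise ParameterError("cluster_sizes length must equal n_clusters")
        if len(self.cluster_fc_means) != self.n_clusters:
            raise ParameterError("cluster_fc_means length must equal n_clusters")
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ParameterError("need 0 <= p_out < p_in <= 1")
        for lo, hi in (self.ppi_in_range, self.ppi_out_range):
            if not 0 <= lo <= hi <= 1:
                raise ParameterError("ppi ranges must satisfy 0 <= lo <= hi <= 1")
        if not (
            any(m > 0 for m in self.cluster_fc_means)
            and any(m < 0 for m in self.cluster_fc_means)
        ):
            raise ParameterError(
                "cluster_fc_means needs at least one positive and one negative centre"
            )
        if self.fc_noise_sd < 0 or self.pheno_noise_sd < 0:
            raise ParameterError("noise SDs must be non-negative")
        total = sum(self.variant_class_probs.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.variant_class_probs.values()):
            raise ParameterError("variant_class_probs must be a probability distribution")
        for cid in self.phenotype_effects:
            if not 0 <= cid < self.n_clusters:
                raise ParameterError(f"phenotype_effects references unknown cluster {cid}")
        if not 0 <= self.multi_gene_prob <= 1:
            raise ParameterError("multi_gene_prob must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted assignments: gene -> cluster, cluster -> (phenotype, sign),
    variant -> (zygosity, tier)."""

    gene_cluster: dict[str, int]
    phenotype_sign: dict[int, tuple[str, str]]
    variant_class: dict[str, tuple[str, str]] = field(default_factory=dict)

    def cluster_members(self, cid: int) -> list[str]:
        return sorted(g for g, c in self.gene_cluster.items() if c == cid)


def _rng(spec: SyntheticSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec.seed, stage)))


def generate_network(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Planted-partition interaction graph and per-gene fold changes.

    Returns (edge table with gene_a/gene_b/ppi_score, fold-change table
    with gene/log2fc/pvalue/fdr, ground truth). Intra-cluster edges are
    drawn with probability p_in and confidence from ppi_in_range;
    inter-cluster edges with p_out and ppi_out_range. Gene log2fc = its
    cluster centre + Gaussian(0, fc_noise_sd).
    """
    rng = _rng(spec, 0)
    genes, cluster_of = [], {}
    for cid, size in enumerate(spec.cluster_sizes):
        for i in range(size):
            name = f"G{len(genes):04d}"
            genes.append(name)
            cluster_of[name] = cid

    edges = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            same = cluster_of[a] == cluster_of[b]
            p = spec.p_in if same else spec.p_out
            if rng.random() < p:
                lo, hi = spec.ppi_in_range if same else spec.ppi_out_range
                edges.append((a, b, float(rng.uniform(lo, hi))))
    edge_df = pd.DataFrame(edges, columns=["gene_a", "gene_b", "ppi_score"])

    log2fc = np.array(
        [
            spec.cluster_fc_means[cluster_of[g]] + rng.normal(0, spec.fc_noise_sd)
            for g in genes
        ]
    )
    fc_df = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "pvalue": np.full(len(genes), 1e-4),
            "fdr": np.full(len(genes), 1e-3),
        }
    )
    truth = GroundTruth(
        gene_cluster=cluster_of,
        phenotype_sign={
            cid: (name, "+" if eff > 0 else "-")
            for cid, (name, eff) in spec.phenotype_effects.items()
        },
    )
    return edge_df, fc_df, truth


def generate_phenotypes(
    fc_df: pd.DataFrame, truth: GroundTruth, spec: SyntheticSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample expression matrix and phenotype table.

    Samples form a balanced two-condition design (first half control,
    second half treated). Expression of gene g in sample s is
    baseline + t_s * log2fc_g + Gaussian(0, fc_noise_sd) with t_s the
    condition indicator, so treated samples shift by the gene's fold
    change. Each phenotype is effect x (mean expression of its driver
    cluster in that sample) + Gaussian(0, pheno_noise_sd).

    Returns (expression genes x samples, phenotypes samples x names).
    """
    if spec.n_samples < 4:
        raise ParameterError("need at least 4 samples")
    for cid in spec.phenotype_effects:
        if cid not in set(truth.gene_cluster.values()):
            raise ParameterError(f"phenotype_effects references unknown cluster {cid}")
    rng = _rng(spec, 1)
    genes = list(fc_df["gene"])
    lfc = fc_df["log2fc"].to_numpy(dtype=float)
    n = spec.n_samples
    t = np.zeros(n)
    t[n // 2 :] = 1.0
    samples = [f"S{j:03d}" for j in range(n)]
    expr = (
        _EXPRESSION_BASELINE
        + np.outer(lfc, t)
        + rng.normal(0, spec.fc_noise_sd, size=(len(genes), n))
    )
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)

    pheno = {}
    for cid, (name, effect) in sorted(spec.phenotype_effects.items()):
        members = truth.cluster_members(cid)
        cluster_mean = expr_df.loc[members].mean(axis=0).to_numpy()
        pheno[name] = effect * cluster_mean + rng.normal(0, spec.pheno_noise_sd, size=n)
    pheno_df = pd.DataFrame(pheno, index=samples)
    return expr_df, pheno_df


def generate_variants(
    genes: list[str], spec: SyntheticSpec, truth: GroundTruth | None = None
) -> tuple[list, pd.DataFrame]:
    """VCF-style variant records plus per-(variant, gene) consequences.

    Each variant draws a (zygosity, impact tier) class from
    ``variant_class_probs``, a genotype realizing the zygosity, and a
    consequence term from the tier's vocabulary. With probability
    ``multi_gene_prob`` a variant is annotated to two genes, so the
    per-gene consequence row count can exceed the distinct variant count.
    """
    from .variants import VariantRecord  # local import to avoid cycle at module load

    rng = _rng(spec, 2)
    classes = sorted(spec.variant_class_probs)
    probs = np.array([spec.variant_class_probs[c] for c in classes])
    draw = rng.choice(len(classes), size=spec.n_variants, p=probs)
    records, cons_rows = [], []
    variant_class: dict[str, tuple[str, str]] = {}
    for i, ci in enumerate(draw):
        zyg, tier = classes[ci]
        pos = 1000 + 10 * i
        alts = ("T",) if zyg != "het_without_ref" else ("T", "G")
        rec = VariantRecord(
            chrom="chrI", pos=pos, ref="A", alts=alts, genotype=_ZYG_GT[zyg]
        )
        records.append(rec)
        variant_class[rec.key] = (zyg, tier)
        term = _TIER_TERMS[tier][int(rng.integers(len(_TIER_TERMS[tier])))]
        n_genes = 2 if rng.random() < spec.multi_gene_prob and len(genes) > 1 else 1
        for g in rng.choice(genes, size=n_genes, replace=False):
            cons_rows.append({"variant": rec.key, "gene": str(g), "consequence": term})
    cons_df = pd.DataFrame(cons_rows, columns=["variant", "gene", "consequence"])
    if truth is not None:
        truth.variant_class = variant_class
    return records, cons_df


def generate_terms(
    truth: GroundTruth, spec: SyntheticSpec, coverage: float = 0.8
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Term memberships and a matching pathway-perturbation table.

    One term per planted cluster containing *coverage* of its genes (so
    over-representation tests can recover the cluster's identity), plus
    one diffuse background term. The perturbation table marks each
    cluster term up/down according to the sign of the cluster's
    fold-change centre, with a significant FDR.
    """
    rng = _rng(spec, 3)
    all_genes = sorted(truth.gene_cluster)
    terms: dict[str, set[str]] = {}
    pert_rows = []
    for cid, centre in enumerate(spec.cluster_fc_means):
        members = truth.cluster_members(cid)
        n_keep = max(1, int(round(coverage * len(members))))
        keep = sorted(rng.choice(members, size=n_keep, replace=False))
        name = f"pathway_C{cid}"
        terms[name] = set(map(str, keep))
        pert_rows.append(
            {
                "pathway": name,
                "direction": "up" if centre > 0 else "down",
                "fold_enrichment": float(len(keep) / max(len(members) * len(keep) / len(all_genes), 1e-9)),
                "fdr": 1e-4,
            }
        )
    background = sorted(rng.choice(all_genes, size=max(2, len(all_genes) // 3), replace=False))
    terms["pathway_background"] = set(map(str, background))
    pert_rows.append(
        {"pathway": "pathway_background", "direction": "up", "fold_enrichment": 1.0, "fdr": 0.9}
    )
    return terms, pd.DataFrame(pert_rows)


@dataclass
class SyntheticDataset:
    """Bundle of all generated pipeline inputs plus the ground truth."""

    spec: SyntheticSpec
    edges: pd.DataFrame
    fold_changes: pd.DataFrame
    expression: pd.DataFrame
    phenotypes: pd.DataFrame
    variant_records: list
    consequences: pd.DataFrame
    terms: dict[str, set[str]]
    perturbations: pd.DataFrame
    truth: GroundTruth
    phenotype_directions: dict[str, str]


def generate_all(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Generate every pipeline input from one spec (one seed)."""
    spec = spec or SyntheticSpec()
    edges, fc, truth = generate_network(spec)
    expr, pheno = generate_phenotypes(fc, truth, spec)
    records, cons = generate_variants(list(fc["gene"]), spec, truth)
    terms, pert = generate_terms(truth, spec)
    directions = {
        name: ("up" if eff > 0 else "down")
        for name, eff in spec.phenotype_effects.values()
    }
    return SyntheticDataset(
        spec=spec, edges=edges, fold_changes=fc, expression=expr, phenotypes=pheno,
        variant_records=records, consequences=cons, terms=terms, perturbations=pert,
        truth=truth, phenotype_directions=directions,
    )
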