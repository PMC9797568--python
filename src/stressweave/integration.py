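"""Signed, directed multi-omics network assembly.

The integration layer joins four evidence types into one typed directed
graph whose directionality follows the causal reading
variant -> gene -> pathway/phenotype:

* gene -> pathway edges for differentially expressed genes that belong to
  a significantly perturbed pathway, weighted +1 when the gene's fold
  change moves with the pathway (both up or both down) and -1 against it;
* gene -> phenotype edges for passing gene–phenotype associations,
  weighted by the association sign;
* variant -> gene edges (weight 0, neutral) for moderate/high-impact
  variants.

Gene nodes carry log2fc, cluster id and the fermentation/ethanol and
ROS/redox flags; phenotype nodes carry the physiology-derived change
direction. The headline sub-network keeps every edge with at least one
endpoint in the anchor set (hub genes plus flagged genes).
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import pandas as pd

from .errors import ParameterError

logger = logging.getLogger(__name__)

NODE_KINDS = ("variant", "gene", "pathway", "phenotype")
RELATIONS = {1: "direct", -1: "inverse", 0: "neutral"}


def edge_sign(gene_log2fc: float, target_direction: str) -> int:
    """+1 when the gene's fold change moves with the target, else -1.

    *target_direction* is "up" (activated/increased) or "down"
    (repressed/decreased). A zero fold change has no direction; callers
    skip the edge.
    """
    if target_direction not in ("up", "down"):
        raise ParameterError(f"target direction must be up/down, got {target_direction!r}")
    if gene_log2fc == 0:
        raise ParameterError("edge sign undefined for zero fold change")
    gene_up = gene_log2fc > 0
    return 1 if gene_up == (target_direction == "up") else -1


def assemble(
    genes: pd.DataFrame,
    memberships: dict[str, set[str]],
    perturbations: pd.DataFrame,
    associations,
    variant_rows: pd.DataFrame,
    phenotype_directions: dict[str, str] | None = None,
    fdr_max: float = 0.01,
) -> nx.DiGraph:
    """Build the integration network.

    Parameters
    ----------
    genes : DataFrame with columns gene, log2fc, cluster and optional
        boolean flags fermentation_ethanol / ros_redox.
    memberships : pathway -> member gene set (GMT-style).
    perturbations : DataFrame with columns pathway, direction (up/down),
        fold_enrichment, fdr. Only pathways with fdr <= fdr_max
        contribute edges.
    associations : iterable of AssociationRecord; only passing records
        with a sign contribute edges.
    variant_rows : classified (variant, gene, tier, zygosity) rows; only
        MODERATE/HIGH tiers create variant nodes.
    phenotype_directions : phenotype -> up/down from the physiology
        comparison, stored as node attributes.

    Dangling references (pathway members, associations or variants naming
    genes absent from *genes*) are collected in ``graph.graph["rejects"]``
    rather than raising.
    """
    for col in ("gene", "log2fc", "cluster"):
        if col not in genes.columns:
            raise ParameterError(f"gene table missing column {col!r}")
    net = nx.DiGraph()
    rejects: list[str] = []
    info = {
        str(r.gene): r for r in genes.itertuples(index=False)
    }

    def _ensure_gene(g: str) -> None:
        if g in net and net.nodes[g]["kind"] == "gene":
            return
        r = info[g]
        net.add_node(
            g,
            kind="gene",
            log2fc=float(r.log2fc),
            cluster=r.cluster,
            fermentation_ethanol=bool(getattr(r, "fermentation_ethanol", False)),
            ros_redox=bool(getattr(r, "ros_redox", False)),
        )

    # gene -> pathway
    sig = perturbations.loc[perturbations["fdr"] <= fdr_max]
    for p in sig.itertuples(index=False):
        members = memberships.get(p.pathway, set())
        for g in sorted(members):
            if g not in info:
                rejects.append(f"pathway {p.pathway} member {g} not a known gene")
                continue
            lfc = float(info[g].log2fc)
            if lfc == 0:
                warnings.warn(
                    f"gene {g} has zero fold change; {g}->{p.pathway} skipped",
                    stacklevel=2,
                )
                continue
            _ensure_gene(g)
            if p.pathway not in net:
                net.add_node(p.pathway, kind="pathway", direction=p.direction)
            w = edge_sign(lfc, p.direction)
            net.add_edge(g, p.pathway, weight=w, relation=RELATIONS[w])

    # gene -> phenotype
    for rec in sorted(associations, key=lambda r: (r.phenotype, r.gene)):
        if not rec.passes or rec.sign is None:
            continue
        if rec.gene not in info:
            rejects.append(f"association names unknown gene {rec.gene}")
            continue
        _ensure_gene(rec.gene)
        if rec.phenotype not in net:
            direction = (phenotype_directions or {}).get(rec.phenotype)
            net.add_node(rec.phenotype, kind="phenotype", direction=direction)
        w = 1 if rec.sign == "+" else -1
        net.add_edge(rec.gene, rec.phenotype, weight=w, relation=RELATIONS[w])

    # variant -> gene
    if len(variant_rows):
        keep = variant_rows.loc[variant_rows["tier"].isin(("MODERATE", "HIGH"))]
        for row in keep.sort_values(["variant", "gene"]).itertuples(index=False):
            if row.gene not in info:
                rejects.append(f"variant {row.variant} annotated to unknown gene {row.gene}")
                continue
            _ensure_gene(row.gene)
            if row.variant not in net:
                net.add_node(
                    row.variant, kind="variant", tier=row.tier, zygosity=row.zygosity
                )
            net.add_edge(row.variant, row.gene, weight=0, relation="neutral")

    net.graph["rejects"] = rejects
    if rejects:
        logger.warning("%d dangling references rejected during assembly", len(rejects))
    return net


def extract_anchor_subnetwork(
    net: nx.DiGraph, hub_genes: set[str], flagged_genes: set[str]
) -> nx.DiGraph:
    """Edges with >= 1 endpoint in (hubs | flagged); isolated nodes dropped.

    Idempotent: extracting twice with the same anchors is a no-op.
    """
    anchors = set(hub_genes) | set(flagged_genes)
    gene_nodes = {n for n, d in net.nodes(data=True) if d.get("kind") == "gene"}
    stray = anchors - gene_nodes
    if stray - set(net.nodes):
        logger.info("anchors absent from network ignored: %s", sorted(stray)[:5])
    sub = nx.DiGraph(**{k: v for k, v in net.graph.items()})
    if not anchors:
        warnings.warn("empty anchor set; extracted network is empty", stacklevel=2)
        return sub
    for u, v, data in net.edges(data=True):
        if u in anchors or v in anchors:
            for node in (u, v):
                if node not in sub:
                    sub.add_node(node, **net.nodes[node])
            sub.add_edge(u, v, **data)
    return sub


def tabulate_model(net: nx.DiGraph) -> pd.DataFrame:
    """One row per connected gene node with its signed links.

    Columns: gene, cluster, log2fc, phenotype_links (e.g. "qEthanol(+)"),
    pathway_links, has_variant, n_positive, n_negative (counts of the
    gene's outgoing +1 / -1 edges). Genes with no edges are excluded.
    """
    rows = []
    for n, data in sorted(net.nodes(data=True)):
        if data.get("kind") != "gene":
            continue
        out_edges = list(net.out_edges(n, data=True))
        in_edges = list(net.in_edges(n, data=True))
        if not out_edges and not in_edges:
            continue
        phen, path = [], []
        npos = nneg = 0
        for _, tgt, ed in sorted(out_edges, key=lambda e: str(e[1])):
            mark = "+" if ed["weight"] > 0 else "-"
            npos += ed["weight"] > 0
            nneg += ed["weight"] < 0
            kind = net.nodes[tgt]["kind"]
            (phen if kind == "phenotype" else path).append(f"{tgt}({mark})")
        rows.append(
            {
                "gene": n,
                "cluster": data.get("cluster"),
                "log2fc": data.get("log2fc"),
                "phenotype_links": ";".join(phen),
                "pathway_links": ";".join(path),
                "has_variant": any(
                    net.nodes[src]["kind"] == "variant" for src, _, _ in in_edges
                ),
                "n_positive": int(npos),
                "n_negative": int(nneg),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "cluster", "log2fc", "phenotype_links", "pathway_links",
            "has_variant", "n_positive", "n_negative",
        ],
    )
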