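"""Per-cluster hub genes and functional labels.

Hub detection ranks every gene inside its cluster's induced subgraph on
four centralities — degree, betweenness, closeness and eigenvector — and
calls a gene a local hub when it reaches the top_k of at least
min_metrics of the four. Functional labelling is classical
over-representation: a hypergeometric upper-tail test of each term's
overlap with the cluster against a gene universe, Benjamini–Hochberg
corrected within the cluster, with the label taken from the most
significant term that also covers at least half the cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

logger = logging.getLogger(__name__)

METRICS = ("degree", "betweenness", "closeness", "eigenvector")


def _eigenvector_scores(sub: nx.Graph) -> dict:
    """Principal adjacency eigenvector, entries >= 0, max-normalized to 1."""
    nodes = sorted(sub.nodes)
    if sub.number_of_edges() == 0:
        return {n: 0.0 for n in nodes}
    a = nx.to_numpy_array(sub, nodelist=nodes)
    vals, vecs = np.linalg.eigh(a)
    vec = np.abs(vecs[:, np.argmax(vals)])
    top = vec.max()
    return {n: float(v / top) if top > 0 else 0.0 for n, v in zip(nodes, vec)}


def centralities(
    graph: nx.Graph, partition: dict[str, int], weighted: bool = False
) -> pd.DataFrame:
    """Four centralities per gene on its cluster's induced subgraph.

    Unweighted topology by default; ``weighted=True`` uses distance
    = 1/enhanced_score for betweenness/closeness and enhanced_score for
    degree (strength). Betweenness is the raw shortest-path pair count
    (unnormalized); closeness is (n-1)/sum of distances within the node's
    component; eigenvector entries are max-normalized per cluster.
    Singletons score 0 on every metric. Adds per-metric within-cluster
    ranks (1 = most central; ties resolved by gene id for determinism).
    """
    rows = []
    clusters: dict[int, list] = {}
    for node, cid in partition.items():
        clusters.setdefault(cid, []).append(node)
    for cid, members in sorted(clusters.items()):
        missing = [m for m in members if m not in graph]
        if missing:
            raise ParameterError(f"cluster {cid} has nodes outside graph: {missing[:5]}")
        sub = graph.subgraph(members)
        if weighted:
            for u, v, data in sub.edges(data=True):
                data["_dist"] = 1.0 / max(data.get("enhanced_score", 1.0), 1e-12)
            deg = dict(sub.degree(weight="enhanced_score"))
            btw = nx.betweenness_centrality(sub, normalized=False, weight="_dist")
            clo = nx.closeness_centrality(sub, distance="_dist")
        else:
            deg = dict(sub.degree())
            btw = nx.betweenness_centrality(sub, normalized=False)
            clo = nx.closeness_centrality(sub)
        eig = _eigenvector_scores(sub)
        for gene in sorted(members):
            rows.append(
                {
                    "gene": gene,
                    "cluster": cid,
                    "degree": float(deg[gene]),
                    "betweenness": float(btw[gene]),
                    "closeness": float(clo[gene]),
                    "eigenvector": eig[gene],
                }
            )
    records = pd.DataFrame(rows)
    for metric in METRICS:
        ranks = np.empty(len(records), dtype=int)
        for _, idx in records.groupby("cluster").groups.items():
            block = records.loc[idx]
            order = block.sort_values([metric, "gene"], ascending=[False, True]).index
            for r, i in enumerate(order, start=1):
                ranks[records.index.get_loc(i)] = r
        records[f"{metric}_rank"] = ranks
    return records


def select_hubs(
    records: pd.DataFrame, top_k: int = 3, min_metrics: int = 3
) -> dict[int, list[str]]:
    """Local hubs per cluster.

    A gene is a hub iff its within-cluster rank is <= *top_k* on at least
    *min_metrics* of the four centralities. Hubs are reported sorted by
    (rank sum over the four metrics, gene id).
    """
    if top_k < 1 or not 1 <= min_metrics <= len(METRICS):
        raise ParameterError("top_k >= 1 and 1 <= min_metrics <= 4 required")
    rank_cols = [f"{m}_rank" for m in METRICS]
    hubs: dict[int, list[str]] = {}
    for cid, block in records.groupby("cluster"):
        hits = (block[rank_cols] <= top_k).sum(axis=1)
        chosen = block.loc[hits >= min_metrics].copy()
        chosen["rank_sum"] = chosen[rank_cols].sum(axis=1)
        chosen = chosen.sort_values(["rank_sum", "gene"])
        hubs[int(cid)] = chosen["gene"].tolist()
    return hubs


@dataclass
class EnrichmentResult:
    cluster: int
    term: str
    overlap: int
    term_size: int
    cluster_size: int
    universe_size: int
    fold_enrichment: float
    pvalue: float
    fdr: float


def enrich_terms(
    cluster_genes: set[str],
    universe: set[str],
    terms: dict[str, set[str]],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in the cluster.

    Terms are intersected with the universe; the cluster must be a subset
    of the universe. p = P(X >= overlap) for X hypergeometric(universe,
    term, cluster); fold enrichment = overlap / expected overlap. FDR is
    Benjamini–Hochberg across the tested terms.
    """
    if not cluster_genes <= universe:
        raise ParameterError("cluster genes must be a subset of the universe")
    if not universe:
        raise ParameterError("empty universe")
    n_u, n_c = len(universe), len(cluster_genes)
    results = []
    for term_id in sorted(terms):
        term_genes = terms[term_id] & universe
        if not term_genes:
            logger.warning("term %s has no genes in universe; skipped", term_id)
            continue
        n_t = len(term_genes)
        k = len(term_genes & cluster_genes)
        p = float(hypergeom.sf(k - 1, n_u, n_t, n_c))
        expected = n_t * n_c / n_u
        results.append(
            EnrichmentResult(
                cluster=-1, term=term_id, overlap=k, term_size=n_t,
                cluster_size=n_c, universe_size=n_u,
                fold_enrichment=k / expected, pvalue=p, fdr=np.nan,
            )
        )
    if results:
        fdrs = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        for r, q in zip(results, fdrs):
            r.fdr = float(q)
    return results


def label_cluster(
    results: list[EnrichmentResult],
    coverage_min: float = 0.5,
    fdr_max: float = 0.01,
) -> str:
    """Functional label: lowest-FDR term with FDR <= fdr_max covering at
    least *coverage_min* of the cluster; ties broken by larger coverage
    then term id. "unlabeled" when nothing qualifies."""
    eligible = [
        r
        for r in results
        if r.fdr <= fdr_max and r.overlap / r.cluster_size >= coverage_min
    ]
    if not eligible:
        return "unlabeled"
    eligible.sort(key=lambda r: (r.fdr, -r.overlap / r.cluster_size, r.term))
    return eligible[0].term
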