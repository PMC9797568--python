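"""Attribute-enhanced interaction graph construction.

Starting from a STRING-style protein–protein interaction edge list and a
table of differential-expression log2 fold changes, this module keeps only
high-confidence interactions (ppi_score >= 0.7 by default), scores each
retained edge by how similarly its two genes respond to the condition
(foldChange_score = 1 - |Xi - Xj| / max_distance, where max_distance is
the largest fold-change gap observed), and combines the two scores into a
single edge weight (enhanced_score) used by the downstream Markov
clustering. The result is an undirected :class:`networkx.Graph` whose
nodes carry ``log2fc`` and whose edges carry ``ppi_score``,
``fold_change_score`` and ``enhanced_score``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import DataError, FormatError, NormalizationError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE = 0.7


@dataclass(frozen=True)
class DEGFilter:
    """Significance thresholds for calling differential expression.

    Defaults follow the edgeR cutoffs used upstream: FDR <= 0.01 and
    |log2FC| >= 0.5. An optional raw p-value cap can be added for the
    stricter variant (p < 0.05, |log2FC| >= 1).
    """

    fdr_max: float = 0.01
    abs_log2fc_min: float = 0.5
    pvalue_max: float | None = None

    def __post_init__(self) -> None:
        if self.fdr_max <= 0 or self.abs_log2fc_min < 0:
            raise ParameterError("DEGFilter thresholds must be positive")
        if self.pvalue_max is not None and self.pvalue_max <= 0:
            raise ParameterError("pvalue_max must be positive when given")


def filter_degs(table: pd.DataFrame, deg_filter: DEGFilter = DEGFilter()) -> pd.DataFrame:
    """Rows of *table* passing all thresholds of *deg_filter*.

    Requires columns ``gene``, ``log2fc``, ``fdr`` (and ``pvalue`` when the
    filter sets a p-value cap). Duplicate gene ids are a data error.
    """
    required = {"gene", "log2fc", "fdr"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"DEG table missing columns: {sorted(missing)}")
    dup = table["gene"][table["gene"].duplicated()]
    if not dup.empty:
        raise DataError(f"duplicate gene ids in DEG table: {sorted(set(dup))[:5]}")
    mask = (table["fdr"] <= deg_filter.fdr_max) & (
        table["log2fc"].abs() >= deg_filter.abs_log2fc_min
    )
    if deg_filter.pvalue_max is not None:
        if "pvalue" not in table.columns:
            raise FormatError("DEG table missing column: ['pvalue']")
        mask &= table["pvalue"] < deg_filter.pvalue_max
    return table.loc[mask].reset_index(drop=True)


def fold_change_score(xi: float, xj: float, max_distance: float) -> float:
    """Similarity of two genes' log2 fold changes, in [0, 1].

    1 for identical fold changes, 0 for the pair realizing *max_distance*
    (the largest fold-change difference in the network).
    """
    diff = abs(xi - xj)
    if max_distance == 0:
        if diff == 0:
            return 1.0
        raise NormalizationError("max_distance is 0 but fold changes differ")
    if max_distance < 0:
        raise ParameterError("max_distance must be non-negative")
    score = 1.0 - diff / max_distance
    if score < -1e-12:
        raise ParameterError("pair difference exceeds max_distance")
    return max(score, 0.0)


def enhanced_score(fc_score: float, ppi_score: float, mode: str = "product") -> float:
    """Combine fold-change similarity and interaction confidence.

    ``product`` (default) multiplies the two scores; ``mean`` averages
    them. Both are monotone in each argument and map [0,1]^2 into [0,1].
    """
    for name, v in (("fold_change_score", fc_score), ("ppi_score", ppi_score)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name}={v} outside [0, 1]")
    if mode == "product":
        return fc_score * ppi_score
    if mode == "mean":
        return (fc_score + ppi_score) / 2.0
    raise ParameterError(f"unknown combination mode {mode!r}")


def build_enhanced_graph(
    edges: pd.DataFrame,
    fold_changes: pd.DataFrame,
    confidence_threshold: float = DEFAULT_CONFIDENCE,
    mode: str = "product",
    normalize_over: str = "edges",
) -> nx.Graph:
    """Assemble the attribute-enhanced graph.

    *edges* needs columns ``gene_a``, ``gene_b``, ``ppi_score`` (STRING
    0–1000 integer scores are rescaled to [0,1] automatically);
    *fold_changes* needs ``gene`` and ``log2fc``. Edges below
    *confidence_threshold*, self-interactions, and edges touching genes
    without a fold-change record are dropped (the drop counts are logged).
    ``normalize_over`` picks the max-distance normalization domain:
    ``"edges"`` (retained edges, default) or ``"pairs"`` (all node pairs).

    Returns a (possibly empty) undirected graph; emptiness is a valid
    result, signalled by ``graph.number_of_edges() == 0``.
    """
    for col in ("gene_a", "gene_b", "ppi_score"):
        if col not in edges.columns:
            raise FormatError(f"edge table missing column {col!r}")
    if normalize_over not in ("edges", "pairs"):
        raise ParameterError("normalize_over must be 'edges' or 'pairs'")
    fc = dict(zip(fold_changes["gene"], fold_changes["log2fc"]))

    scores = edges["ppi_score"].astype(float)
    if len(scores) and scores.max() > 1.0:  # STRING 0-1000 dialect
        scores = scores / 1000.0
        logger.info("rescaled ppi scores from 0-1000 to [0,1]")

    g = nx.Graph()
    n_low, n_unknown = 0, 0
    for (a, b), s in zip(zip(edges["gene_a"], edges["gene_b"]), scores):
        if a == b:
            continue
        if s < confidence_threshold:
            n_low += 1
            continue
        if a not in fc or b not in fc:
            n_unknown += 1
            continue
        g.add_edge(a, b, ppi_score=float(s))
    if n_low or n_unknown:
        logger.warning(
            "dropped %d low-confidence edges and %d edges touching genes "
            "without fold-change records",
            n_low,
            n_unknown,
        )
    nx.set_node_attributes(g, {n: float(fc[n]) for n in g.nodes}, "log2fc")

    if g.number_of_edges() == 0:
        logger.warning("no edges survive the confidence/fold-change filters")
        return g

    if normalize_over == "edges":
        max_distance = max(abs(fc[u] - fc[v]) for u, v in g.edges)
    else:
        nodes = list(g.nodes)
        max_distance = max(
            abs(fc[u] - fc[v]) for i, u in enumerate(nodes) for v in nodes[i + 1 :]
        )
    for u, v, data in g.edges(data=True):
        fcs = fold_change_score(fc[u], fc[v], max_distance)
        data["fold_change_score"] = fcs
        data["enhanced_score"] = enhanced_score(fcs, data["ppi_score"], mode)
    g.graph["max_distance"] = max_distance
    g.graph["score_mode"] = mode
    return g
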