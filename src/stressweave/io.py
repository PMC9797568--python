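"""Readers and writers for the pipeline's file dialects.

Plain-text formats only: edge TSV (gene_a, gene_b, ppi_score — STRING's
protein1/protein2/combined_score header is accepted too), DEG TSV, GMT
term memberships, minimal VCF v4.2 with a GT FORMAT field (read through
pysam), consequence TSV, phenotype/expression tables, physiology CSV,
GraphML and a node-link JSON for networks. Every writer's output is
parseable by its reader without loss of the in-scope fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
import pysam

from .errors import FormatError
from .variants import VariantRecord

_EDGE_ALIASES = {"protein1": "gene_a", "protein2": "gene_b", "combined_score": "ppi_score"}
_DEG_ALIASES = {
    "log2foldchange": "log2fc", "log2fc": "log2fc", "logfc": "log2fc",
    "fdr": "fdr", "pvalue": "pvalue", "p_value": "pvalue", "gene": "gene",
}


def _read_table(path, sep, what) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{what} file not found: {path}")
    try:
        return pd.read_csv(path, sep=sep)
    except Exception as exc:  # malformed dialect
        raise FormatError(f"cannot parse {what} file {path}: {exc}") from exc


def read_edges(path) -> pd.DataFrame:
    """Interaction edge TSV -> columns gene_a, gene_b, ppi_score."""
    df = _read_table(path, "\t", "edge")
    df = df.rename(columns={c: _EDGE_ALIASES.get(c, c) for c in df.columns})
    missing = {"gene_a", "gene_b", "ppi_score"} - set(df.columns)
    if missing:
        raise FormatError(f"edge file {path} missing columns: {sorted(missing)}")
    if not pd.api.types.is_numeric_dtype(df["ppi_score"]):
        bad = df.index[pd.to_numeric(df["ppi_score"], errors="coerce").isna()]
        raise FormatError(
            f"edge file {path}: non-numeric ppi_score at line {int(bad[0]) + 2}"
        )
    return df[["gene_a", "gene_b", "ppi_score"]]


def read_degs(path) -> pd.DataFrame:
    """Differential-expression TSV -> gene, log2fc[, pvalue], fdr."""
    df = _read_table(path, "\t", "DEG")
    df = df.rename(columns={c: _DEG_ALIASES.get(c.lower(), c) for c in df.columns})
    missing = {"gene", "log2fc", "fdr"} - set(df.columns)
    if missing:
        raise FormatError(f"DEG file {path} missing columns: {sorted(missing)}")
    cols = ["gene", "log2fc", "fdr"] + (["pvalue"] if "pvalue" in df.columns else [])
    return df[cols]


def read_gmt(path) -> dict[str, set[str]]:
    """GMT file -> term name -> gene set (description column ignored)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"GMT file not found: {path}")
    terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT file {path} line {lineno}: need name, description, genes")
        terms[parts[0]] = {g for g in parts[2:] if g}
    return terms


def read_vcf(path) -> list[VariantRecord]:
    """Minimal VCF v4.x with one sample carrying a GT field."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"VCF file not found: {path}")
    records = []
    try:
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            if not samples:
                raise FormatError(f"VCF {path} has no sample column")
            for rec in vcf:
                gt = rec.samples[samples[0]].get("GT")
                if gt is None:
                    raise FormatError(f"VCF {path} record {rec.chrom}:{rec.pos} lacks GT")
                sep = "|" if rec.samples[samples[0]].phased else "/"
                gt_str = sep.join("." if a is None else str(a) for a in gt)
                records.append(
                    VariantRecord(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                        alts=tuple(rec.alts or ()), genotype=gt_str,
                    )
                )
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    return records


def read_consequences(path) -> pd.DataFrame:
    """Consequence TSV -> variant, gene, consequence."""
    df = _read_table(path, "\t", "consequence")
    missing = {"variant", "gene", "consequence"} - set(df.columns)
    if missing:
        raise FormatError(f"consequence file {path} missing columns: {sorted(missing)}")
    return df[["variant", "gene", "consequence"]]


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype CSV (rows = samples, columns = phenotypes)."""
    df = _read_table(path, ",", "phenotype")
    return df.set_index(df.columns[0]).rename_axis("sample")


def read_expression(path) -> pd.DataFrame:
    """Expression TSV (rows = genes, columns = samples), log2 scale."""
    df = _read_table(path, "\t", "expression")
    return df.set_index(df.columns[0]).rename_axis("gene")


def read_physiology(path) -> pd.DataFrame:
    """Physiology CSV -> parameter, control, treated (extra columns kept)."""
    df = _read_table(path, ",", "physiology")
    missing = {"parameter", "control", "treated"} - set(df.columns)
    if missing:
        raise FormatError(f"physiology file {path} missing columns: {sorted(missing)}")
    return df


# --- writers -----------------------------------------------------------


def write_edges(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_degs(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_gmt(terms: dict[str, set[str]], path) -> None:
    lines = [
        "\t".join([name, "synthetic"] + sorted(genes))
        for name, genes in sorted(terms.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf(records: list[VariantRecord], path, sample: str = "sample1") -> None:
    """Minimal uncompressed VCF v4.2 with a single GT-bearing sample."""
    chroms = sorted({r.chrom for r in records})
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={c}>" for c in chroms]
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    body = [
        "\t".join(
            [r.chrom, str(r.pos), ".", r.ref, ",".join(r.alts) or ".",
             ".", "PASS", ".", "GT", r.genotype]
        )
        for r in sorted(records, key=lambda r: (r.chrom, r.pos))
    ]
    Path(path).write_text("\n".join(header + body) + "\n")


def write_consequences(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.rename_axis("sample").to_csv(path)


def write_expression(df: pd.DataFrame, path) -> None:
    df.rename_axis("gene").to_csv(path, sep="\t")


def write_graphml(graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"GraphML file not found: {path}")
    return nx.read_graphml(path)


def write_edge_attributes(graph: nx.Graph, path) -> None:
    """Edge-attribute TSV (gene_a, gene_b, ppi/fold-change/enhanced scores)."""
    rows = [
        {
            "gene_a": u, "gene_b": v,
            "ppi_score": d.get("ppi_score"),
            "fold_change_score": d.get("fold_change_score"),
            "enhanced_score": d.get("enhanced_score"),
        }
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_network_json(net: nx.DiGraph, path) -> None:
    """Node-link JSON document (node kind; weight + relation per edge)."""
    doc = nx.node_link_data(net, edges="links")
    Path(path).write_text(json.dumps(doc, indent=1, default=str))
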