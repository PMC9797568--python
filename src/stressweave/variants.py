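"""Short-variant zygosity and predicted-impact profiling.

Diploid genotypes are classified into three zygosity classes: homozygous
(both alleles carry the same variant), heterozygous-with-reference (one
variant allele, one reference) and heterozygous-without-reference (two
distinct variant alleles). Predicted coding consequences (VEP-style
vocabulary) map onto four severity tiers — MODIFIER < LOW < MODERATE <
HIGH. One variant may be annotated against several genes, so per-(variant,
gene) consequence rows can outnumber distinct variants.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

HOMOZYGOUS = "homozygous"
HET_WITH_REF = "het_with_ref"
HET_WITHOUT_REF = "het_without_ref"
ZYGOSITY_CLASSES = (HOMOZYGOUS, HET_WITH_REF, HET_WITHOUT_REF)

TIERS = ("MODIFIER", "LOW", "MODERATE", "HIGH")
_SEVERITY = {t: i for i, t in enumerate(TIERS)}

#: VEP-style consequence term -> impact tier.
IMPACT_MAP: dict[str, str] = {
    # HIGH: protein-truncating / splice-disrupting
    "frameshift_variant": "HIGH",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "transcript_ablation": "HIGH",
    # MODERATE: protein-altering, length/structure preserved
    "missense_variant": "MODERATE",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "protein_altering_variant": "MODERATE",
    # LOW: coding but largely silent
    "synonymous_variant": "LOW",
    "splice_region_variant": "LOW",
    "stop_retained_variant": "LOW",
    "start_retained_variant": "LOW",
    "incomplete_terminal_codon_variant": "LOW",
    # MODIFIER: non-coding context
    "intron_variant": "MODIFIER",
    "5_prime_UTR_variant": "MODIFIER",
    "3_prime_UTR_variant": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
    "non_coding_transcript_variant": "MODIFIER",
    "non_coding_transcript_exon_variant": "MODIFIER",
}

_GT_RE = re.compile(r"^(\.|\d+)([/|])(\.|\d+)$")


def classify_zygosity(genotype: str, where: str = "") -> str | None:
    """Zygosity class of a diploid genotype string, or None.

    Accepts "a/b" or "a|b" (phasing is ignored — zygosity is unordered).
    Homozygous reference "0/0" and missing "./." return None (no variant
    carried). Non-diploid or malformed genotypes raise FormatError.
    """
    m = _GT_RE.match(genotype.strip())
    if not m:
        if re.match(r"^(\.|\d+)([/|](\.|\d+)){2,}$", genotype.strip()):
            raise FormatError(f"non-diploid genotype {genotype!r} {where}".strip())
        raise FormatError(f"malformed genotype {genotype!r} {where}".strip())
    a_s, _, b_s = m.group(1), m.group(2), m.group(3)
    if "." in (a_s, b_s):
        return None
    a, b = int(a_s), int(b_s)
    if a == 0 and b == 0:
        return None
    if a == b:
        return HOMOZYGOUS
    if 0 in (a, b):
        return HET_WITH_REF
    return HET_WITHOUT_REF


def impact_tier(consequence: str, strict: bool = True) -> str:
    """Impact tier for a VEP-style consequence term.

    Compound terms ("a&b") take the most severe constituent. Unknown
    terms raise ParameterError when *strict*, else fall back to MODIFIER
    with a warning.
    """
    parts = [p.strip() for p in consequence.split("&") if p.strip()]
    tiers = []
    for part in parts:
        if part in IMPACT_MAP:
            tiers.append(IMPACT_MAP[part])
        elif strict:
            raise ParameterError(f"unknown consequence term {part!r}")
        else:
            logger.warning("unknown consequence term %r treated as MODIFIER", part)
            tiers.append("MODIFIER")
    if not tiers:
        raise ParameterError(f"empty consequence term {consequence!r}")
    return max(tiers, key=_SEVERITY.get)


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    genotype: str
    zygosity: str | None = None

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}"


def classify_records(records: list[VariantRecord]) -> list[VariantRecord]:
    """Fill ``zygosity`` in place (and return the list) for each record."""
    for rec in records:
        rec.zygosity = classify_zygosity(
            rec.genotype, where=f"at {rec.chrom}:{rec.pos}"
        )
    return records


def gene_impact_table(
    records: list[VariantRecord],
    consequences: pd.DataFrame,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-(variant, gene) classified rows.

    *consequences* needs columns ``variant`` (key "chrom:pos:ref"),
    ``gene``, ``consequence``. When one (variant, gene) pair carries
    several terms, the most severe tier wins. Output columns: variant,
    gene, consequence, tier, zygosity. Rows for reference/missing
    genotypes are dropped.
    """
    for col in ("variant", "gene", "consequence"):
        if col not in consequences.columns:
            raise FormatError(f"consequence table missing column {col!r}")
    zyg = {r.key: r.zygosity for r in classify_records(records)}
    rows = []
    for rec in consequences.itertuples(index=False):
        if rec.variant not in zyg:
            logger.warning("consequence row for unknown variant %s", rec.variant)
            continue
        if zyg[rec.variant] is None:
            continue
        rows.append(
            {
                "variant": rec.variant,
                "gene": rec.gene,
                "consequence": rec.consequence,
                "tier": impact_tier(rec.consequence, strict=strict),
                "zygosity": zyg[rec.variant],
            }
        )
    df = pd.DataFrame(rows, columns=["variant", "gene", "consequence", "tier", "zygosity"])
    if df.empty:
        return df
    # most severe tier wins per (variant, gene)
    df["_sev"] = df["tier"].map(_SEVERITY)
    df = (
        df.sort_values(["variant", "gene", "_sev"], ascending=[True, True, False])
        .drop_duplicates(["variant", "gene"], keep="first")
        .drop(columns="_sev")
        .reset_index(drop=True)
    )
    return df


def summarize_variants(table: pd.DataFrame) -> dict:
    """Contingency summaries of classified (variant, gene) rows.

    Returns a dict with ``zygosity_by_tier`` (3x4 count table),
    ``consequence_by_tier`` (term counts within each tier),
    ``n_distinct_variants`` and ``n_rows`` (the latter may exceed the
    former because one variant can impact several genes).
    """
    zyg_tier = pd.DataFrame(0, index=list(ZYGOSITY_CLASSES), columns=list(TIERS))
    cons: dict[str, dict[str, int]] = {t: {} for t in TIERS}
    if not table.empty:
        counts = table.groupby(["zygosity", "tier"]).size()
        for (z, t), c in counts.items():
            zyg_tier.loc[z, t] = int(c)
        for t, block in table.groupby("tier"):
            cons[t] = block["consequence"].value_counts().to_dict()
    return {
        "zygosity_by_tier": zyg_tier,
        "consequence_by_tier": cons,
        "n_distinct_variants": 0 if table.empty else int(table["variant"].nunique()),
        "n_rows": int(len(table)),
    }
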