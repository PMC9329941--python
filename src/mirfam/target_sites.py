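"""Overlap of 3'UTR variants with predicted miRNA binding sites.

Predicted sites (TargetScan-style) carry a conservation class — broadly
conserved across vertebrates, conserved across mammals, or poorly
conserved — and a context++ score (CS), where more negative means
stronger predicted repression.  Only broadly conserved or conserved sites
with CS below a cutoff (default -0.4) count as high-confidence; the CS
test is applied per site, not per gene aggregate.

Site coordinates are genomic (already projected through the transcript
model by the annotation source); no UTR-relative arithmetic is done here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import ExpressionRecord, VariantRecord
from .filters import is_brain_expressed

__all__ = [
    "CONSERVED_CLASSES",
    "TargetSite",
    "UtrVariantHit",
    "sites_from_table",
    "site_qualifies",
    "overlap_utr_variants",
    "mirna_target_genes",
]

CONSERVED_CLASSES = frozenset({"broadly_conserved", "conserved"})


@dataclass(frozen=True)
class TargetSite:
    """A predicted miRNA binding site within a gene's 3'UTR."""

    gene: str
    transcript: str
    chrom: str
    start: int  # 0-based half-open genomic coordinates
    end: int
    strand: str
    mirna_family: str
    conservation_class: str
    context_score: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty or inverted site interval")
        if self.conservation_class not in CONSERVED_CLASSES | {"poorly_conserved"}:
            raise ValueError(f"unknown conservation class {self.conservation_class!r}")


@dataclass(frozen=True)
class UtrVariantHit:
    """A variant whose footprint intersects a qualifying binding site."""

    variant_key: tuple
    gene: str
    mirna_family: str
    conservation_class: str
    context_score: float


def sites_from_table(df: pd.DataFrame) -> list[TargetSite]:
    """Build TargetSite objects from a normalized target-site table."""
    return [
        TargetSite(
            gene=row.gene,
            transcript=row.transcript,
            chrom=row.chrom,
            start=int(row.utr_start),
            end=int(row.utr_end),
            strand=row.strand,
            mirna_family=row.mirna_family,
            conservation_class=row.conservation_class,
            context_score=float(row.context_score),
        )
        for row in df.itertuples(index=False)
    ]


def site_qualifies(site: TargetSite, cs_max: float = -0.4) -> bool:
    """High-confidence site: conserved class and CS strictly below cutoff."""
    return site.conservation_class in CONSERVED_CLASSES and site.context_score < cs_max


def overlap_utr_variants(
    variants: list[VariantRecord],
    sites: list[TargetSite],
    cs_max: float = -0.4,
) -> list[UtrVariantHit]:
    """Intersect variant footprints with high-confidence binding sites.

    One hit per (variant, site) pair whose genomic footprints intersect,
    restricted to qualifying sites; a variant hitting two sites of the
    same gene yields two hits (candidate genes are deduplicated later).
    """
    trees: dict[str, IntervalTree] = {}
    for site in sites:
        if site_qualifies(site, cs_max):
            trees.setdefault(site.chrom, IntervalTree()).addi(site.start, site.end, site)
    hits: list[UtrVariantHit] = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        overlapped = sorted(
            (iv.data for iv in tree.overlap(v.start, v.end)),
            key=lambda s: (s.start, s.end, s.gene, s.mirna_family),
        )
        for site in overlapped:
            hits.append(
                UtrVariantHit(
                    variant_key=v.key,
                    gene=site.gene,
                    mirna_family=site.mirna_family,
                    conservation_class=site.conservation_class,
                    context_score=site.context_score,
                )
            )
    return hits


def mirna_target_genes(
    mirna_family: str,
    sites: list[TargetSite],
    expression_records: dict[str, list[ExpressionRecord]],
    cs_max: float = -0.4,
    tpm_min: float = 5.0,
) -> set[str]:
    """Brain-expressed predicted target genes of one miRNA family.

    Genes with at least one qualifying site for the family, intersected
    with genes brain-expressed under the TPM rule.  An unknown family
    yields an empty set.
    """
    genes = {
        s.gene for s in sites if s.mirna_family == mirna_family and site_qualifies(s, cs_max)
    }
    return {g for g in genes if is_brain_expressed(g, expression_records, tpm_min)}
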