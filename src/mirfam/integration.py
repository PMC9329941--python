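"""Candidate assembly, cross-family summaries, and GO over-representation.

Combines the two evidence streams — variants inside miRNAs and variants
inside predicted 3'UTR binding sites — into per-phenotype candidate
tables, counts unique genes per phenotype and inheritance mode (marginals
are set unions, never sums), partitions families by the exact phenotype
combination they support (Venn cells), flags genes with dual evidence or
recurrence across families and phenotypes, and tests candidate gene
lists for Gene Ontology term over-representation with a one-sided
hypergeometric test and Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CandidateCall",
    "EnrichmentResult",
    "summarize_by_phenotype",
    "family_venn",
    "dual_evidence_genes",
    "recurrent_genes",
    "go_overrepresentation",
]


@dataclass(frozen=True)
class CandidateCall:
    """One fully filtered candidate: a variant tied to a gene (3'UTR
    stream) or a miRNA (miRNA stream), a family, a phenotype and an
    inheritance mode.  ``af_summary`` is the maximum AF observed across
    reference datasets (None when absent from all)."""

    variant_key: tuple
    source: str  # "mirna" | "utr"
    gene: str  # gene symbol, or precursor miRNA name for source="mirna"
    family_id: str
    phenotype: str
    mode: str
    af_summary: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("mirna", "utr"):
            raise ValueError(f"unknown candidate source {self.source!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    overlap_count: int
    term_size: int
    query_size: int
    p_value: float
    q_value: float
    enriched: bool


def summarize_by_phenotype(
    calls: list[CandidateCall],
    phenotypes: list[str] | None = None,
    modes: list[str] = ["dominant", "recessive", "de_novo"],
) -> pd.DataFrame:
    """Unique-gene counts per (mode, phenotype) with union marginals.

    Rows are inheritance modes plus a ``total_unique`` row; columns are
    phenotypes plus a ``total_unique`` column.  Every marginal is the
    cardinality of the union of the corresponding gene sets, so it can be
    smaller than the sum across the row or column (one gene may appear
    under several modes or phenotypes).
    """
    if phenotypes is None:
        phenotypes = sorted({c.phenotype for c in calls})
    sets: dict[tuple[str, str], set[str]] = {
        (m, p): set() for m in modes for p in phenotypes
    }
    for c in calls:
        if c.mode in modes and c.phenotype in phenotypes:
            sets[(c.mode, c.phenotype)].add(c.gene)
    data = {}
    for p in phenotypes:
        col = [len(sets[(m, p)]) for m in modes]
        col.append(len(set().union(*(sets[(m, p)] for m in modes))))
        data[p] = col
    row_unions = [set().union(*(sets[(m, p)] for p in phenotypes)) for m in modes]
    total = set().union(*row_unions) if row_unions else set()
    data["total_unique"] = [len(u) for u in row_unions] + [len(total)]
    return pd.DataFrame(data, index=modes + ["total_unique"])


def family_venn(calls: list[CandidateCall], mode: str) -> dict[frozenset[str], int]:
    """Partition families by the exact phenotype set they support in one mode.

    Each family is counted exactly once, in the cell of its full
    phenotype combination; cell counts therefore sum to the number of
    families with at least one call in the mode.
    """
    by_family: dict[str, set[str]] = {}
    for c in calls:
        if c.mode == mode:
            by_family.setdefault(c.family_id, set()).add(c.phenotype)
    venn: dict[frozenset[str], int] = {}
    for phenos in by_family.values():
        cell = frozenset(phenos)
        venn[cell] = venn.get(cell, 0) + 1
    return venn


def dual_evidence_genes(
    mirna_target_sets: dict[str, set[str]],
    utr_calls: list[CandidateCall],
) -> pd.DataFrame:
    """Genes supported by both evidence streams.

    A gene qualifies when it is a predicted target of at least one
    candidate miRNA *and* carries a filtered variant in its own 3'UTR
    binding sites.  The returned table carries both evidence trails: the
    targeting miRNAs and the 3'UTR families/phenotypes.
    """
    target_union: dict[str, list[str]] = {}
    for mirna, genes in mirna_target_sets.items():
        for g in genes:
            target_union.setdefault(g, []).append(mirna)
    utr_by_gene: dict[str, list[CandidateCall]] = {}
    for c in utr_calls:
        if c.source != "utr":
            raise ValueError("utr_calls must contain only source='utr' candidates")
        utr_by_gene.setdefault(c.gene, []).append(c)
    rows = []
    for gene in sorted(set(target_union) & set(utr_by_gene)):
        calls = utr_by_gene[gene]
        rows.append(
            {
                "gene": gene,
                "targeting_mirnas": ";".join(sorted(set(target_union[gene]))),
                "utr_families": ";".join(sorted({c.family_id for c in calls})),
                "utr_phenotypes": ",".join(sorted({c.phenotype for c in calls})),
                "utr_modes": ",".join(sorted({c.mode for c in calls})),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "targeting_mirnas", "utr_families", "utr_phenotypes", "utr_modes"])


def recurrent_genes(
    utr_calls: list[CandidateCall],
    min_families: int = 2,
    min_phenotypes: int = 2,
) -> list[str]:
    """Genes whose 3'UTR calls span at least ``min_families`` distinct
    families and ``min_phenotypes`` distinct phenotypes."""
    fams: dict[str, set[str]] = {}
    phenos: dict[str, set[str]] = {}
    for c in utr_calls:
        fams.setdefault(c.gene, set()).add(c.family_id)
        phenos.setdefault(c.gene, set()).add(c.phenotype)
    return sorted(
        g for g in fams if len(fams[g]) >= min_families and len(phenos[g]) >= min_phenotypes
    )


def go_overrepresentation(
    query_genes: set[str],
    annotation: pd.DataFrame,
    background: set[str] | None = None,
    max_term_size: int = 600,
    q_max: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of GO-style terms.

    ``annotation`` has columns term_id, term_name, gene.  The background
    defaults to all genes in the annotation table; the query must be a
    subset of the background.  Terms with ``max_term_size`` or more genes
    (within the background) are excluded before testing.  P-values are
    the exact upper tail P(X >= k) of the hypergeometric distribution;
    q-values are Benjamini-Hochberg across the tested terms, and a term
    is flagged enriched when q < ``q_max``.
    """
    if background is None:
        background = set(annotation["gene"])
    if not background:
        raise ValueError("empty enrichment background")
    stray = query_genes - background
    if stray:
        raise ValueError(f"query genes absent from background: {sorted(stray)[:5]}")
    n_bg = len(background)
    n_query = len(query_genes)
    term_genes: dict[tuple[str, str], set[str]] = {}
    for row in annotation.itertuples(index=False):
        if row.gene in background:
            term_genes.setdefault((row.term_id, row.term_name), set()).add(row.gene)
    tested = [
        (tid, tname, genes)
        for (tid, tname), genes in sorted(term_genes.items())
        if len(genes) < max_term_size
    ]
    if not tested:
        return []
    pvals = []
    for tid, tname, genes in tested:
        k = len(genes & query_genes)
        # upper tail P(X >= k) with X ~ Hypergeom(N=n_bg, K=len(genes), n=n_query)
        pvals.append(hypergeom.sf(k - 1, n_bg, len(genes), n_query))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = []
    for (tid, tname, genes), p, q in zip(tested, pvals, qvals):
        k = len(genes & query_genes)
        results.append(
            EnrichmentResult(
                term_id=tid,
                term_name=tname,
                overlap_count=k,
                term_size=len(genes),
                query_size=n_query,
                p_value=float(p),
                q_value=float(q),
                enriched=bool(q < q_max),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
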