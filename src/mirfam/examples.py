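"""Worked-example candidate tables from a family-cohort study of ASD and
related neurodevelopmental phenotypes.

These small tables reproduce the published candidate rows of such a
study — five dominant miRNA variants with their reference-population
allele frequencies in three gnomAD-style non-neuro datasets, and six top
candidate genes with miRNA-target and/or 3'UTR-variant evidence — and
are used in the documentation and as fixed regression inputs: running
the package's AF filter and integration operations on them must recover
the study's own headline counts (five AF-passing miRNA variants, four
dual-evidence genes, two multi-family multi-phenotype genes).
"""

from __future__ import annotations

from .integration import CandidateCall
from .io_formats import AfRecord, variant_key

__all__ = [
    "MIRNA_CANDIDATE_ROWS",
    "TOP_GENE_ROWS",
    "example_af_records",
    "example_utr_calls",
    "example_mirna_target_sets",
]

#: Five dominant miRNA candidate variants: reference AFs are per-dataset
#: (v2 exome non-neuro, v2 genome non-neuro, v3 non-neuro); None = the
#: dataset reports no frequency for the variant.
MIRNA_CANDIDATE_ROWS = [
    {
        "mirna": "hsa-miR-6780a-3p", "region": "seed",
        "chrom": "chr17", "pos": 40860121, "ref": "A", "alt": "G",
        "rsid": "rs200279579", "afs": (1.23e-4, 9.42e-5, 1.26e-4),
        "family": "FAM5", "mode": "dominant", "phenotype": "RI",
    },
    {
        "mirna": "hsa-miR-1225-5p", "region": "mature",
        "chrom": "chr16", "pos": 2140269, "ref": "C", "alt": "A",
        "rsid": "rs371749301", "afs": (1.48e-5, 4.72e-5, 2.00e-4),
        "family": "FAM58", "mode": "dominant", "phenotype": "RI",
    },
    {
        "mirna": "hsa-miR-2277-3p", "region": "mature",
        "chrom": "chr5", "pos": 92956416, "ref": "G", "alt": "T",
        "rsid": "rs550720421", "afs": (4.62e-4, 4.24e-4, 8.83e-4),
        "family": "FAM58", "mode": "dominant", "phenotype": "RI",
    },
    {
        "mirna": "hsa-miR-548j-5p", "region": "mature",
        "chrom": "chr22", "pos": 26951249, "ref": "C", "alt": "T",
        "rsid": "rs565141718", "afs": (3.95e-4, 4.70e-5, 1.41e-4),
        "family": "FAM13", "mode": "dominant", "phenotype": "LI",
    },
    {
        "mirna": "hsa-miR-100-5p", "region": "mature",
        "chrom": "chr11", "pos": 122022992, "ref": "G", "alt": "A",
        "rsid": "rs761222509", "afs": (1.93e-5, None, 7.42e-6),
        "family": "FAM66", "mode": "dominant", "phenotype": "RI",
    },
]

_AF_DATASETS = (
    "gnomad_v2_exome_nonneuro",
    "gnomad_v2_genome_nonneuro",
    "gnomad_v3_nonneuro",
)

#: Six top candidate genes.  ``mirna`` is the targeting candidate miRNA
#: (None when the gene has 3'UTR evidence only); the 3'UTR evidence is a
#: variant with its carrying families and segregating phenotypes.
TOP_GENE_ROWS = [
    {
        "gene": "ONECUT2", "mirna": "hsa-miR-6780a-3p",
        "utr": {"chrom": "chr18", "pos": 55155836, "rsid": "rs147208471",
                "af_gnomad": 7.27e-4, "mode": "dominant",
                "families": ["FAM56"], "phenotypes": ["SRS"]},
    },
    {
        "gene": "OSBP", "mirna": "hsa-miR-6780a-3p",
        "utr": {"chrom": "chr11", "pos": 59343007, "rsid": "rs149325846",
                "af_gnomad": 3.61e-3, "mode": "dominant",
                "families": ["FAM14", "FAM66"], "phenotypes": ["RI"]},
    },
    {
        "gene": "SCP2", "mirna": "hsa-miR-6780a-3p",
        "utr": {"chrom": "chr1", "pos": 53516762, "rsid": "rs182947399",
                "af_gnomad": 1.33e-3, "mode": "dominant",
                "families": ["FAM2"], "phenotypes": ["ADHD"]},
    },
    {
        "gene": "TUB", "mirna": "hsa-miR-6780a-3p",
        "utr": {"chrom": "chr11", "pos": 8123523, "rsid": "rs1379616749",
                "af_gnomad": 3.12e-4, "mode": "dominant",
                "families": ["FAM70"], "phenotypes": ["RI"]},
    },
    {
        "gene": "RBM24", "mirna": None,
        "utr": {"chrom": "chr6", "pos": 17292448, "rsid": "rs914886490",
                "af_gnomad": 2.60e-4, "mode": "de_novo",
                "families": ["FAM5", "FAM59"], "phenotypes": ["ADHD", "LI"]},
    },
    {
        "gene": "UGCG", "mirna": None,
        "utr": {"chrom": "chr9", "pos": 114695431, "rsid": "rs201977317",
                "af_gnomad": 4.54e-3, "mode": "dominant",
                "families": ["FAM5", "FAM36", "FAM37"], "phenotypes": ["RI", "SRS"]},
    },
]


def example_af_records() -> dict[tuple, list[AfRecord]]:
    """Per-variant reference-AF records for the five miRNA candidates."""
    out: dict[tuple, list[AfRecord]] = {}
    for row in MIRNA_CANDIDATE_ROWS:
        key = variant_key(row["chrom"], row["pos"], row["ref"], row["alt"])
        out[key] = [
            AfRecord(key=key, dataset_id=ds, af=af)
            for ds, af in zip(_AF_DATASETS, row["afs"])
        ]
    return out


def example_utr_calls() -> list[CandidateCall]:
    """3'UTR candidate calls for the six top genes, one call per
    (family, phenotype) combination listed for the gene's variant."""
    calls = []
    for row in TOP_GENE_ROWS:
        utr = row["utr"]
        key = variant_key(utr["chrom"], utr["pos"], "N", "V")
        for fam in utr["families"]:
            for pheno in utr["phenotypes"]:
                calls.append(
                    CandidateCall(
                        variant_key=key,
                        source="utr",
                        gene=row["gene"],
                        family_id=fam,
                        phenotype=pheno,
                        mode=utr["mode"],
                        af_summary=utr["af_gnomad"],
                    )
                )
    return calls


def example_mirna_target_sets() -> dict[str, set[str]]:
    """Candidate-miRNA target sets implied by the top-gene table."""
    sets: dict[str, set[str]] = {}
    for row in TOP_GENE_ROWS:
        if row["mirna"] is not None:
            sets.setdefault(row["mirna"], set()).add(row["gene"])
    return sets
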