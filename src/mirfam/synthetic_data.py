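"""Synthetic family cohort and annotation generator with planted truth.

Generates every input the pipeline consumes — pedigree, genotypes,
miRNA annotation, 3'UTR/target-site tables, population allele-frequency
(AF) tables, brain-expression tables, PPI edge lists, GO annotations —
as internally consistent files on one synthetic chromosome, together
with a truth table stating, for every planted variant, which funnel
stages it is expected to survive.

The default configuration mirrors the shape of a realistic
multi-phenotype family cohort: 73 families totalling 272 sequenced
individuals (a mixture of trios, quads, and three-generation families),
five phenotypes with per-role prevalences, and parents never affected
for ASD — which makes ASD-dominant plants infeasible by construction
and requesting one raises an error.

Planted variants are placed one per family.  Within a plant's family
the affection pattern and genotypes are set to realize its inheritance
mode exactly (and all other phenotypes are set unaffected there, so a
plant segregates only for its designated phenotype); everywhere else
the alternate allele is absent.  Background variants are placed in
intergenic space (so they never enter either funnel), with founder
genotypes drawn from stratified population frequencies and child
genotypes produced by Mendelian transmission.  Apart from planted de
novo alleles, every generated genotype is Mendelian-consistent.

All randomness flows from ``SimConfig.rng_seed``; the same configuration
produces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    Affection,
    Pedigree,
    Sample,
    VariantRecord,
    write_interval_table,
    write_ped,
)

__all__ = [
    "PHENOTYPES",
    "AF_DATASETS",
    "EXPR_DATASETS",
    "PPI_DATABASES",
    "PlantSpec",
    "SimConfig",
    "default_plants",
    "SyntheticBundle",
    "simulate_cohort",
    "simulate_annotations",
    "simulate_bundle",
    "write_bundle",
    "write_vcf",
]

PHENOTYPES: tuple[str, ...] = ("ASD", "LI", "RI", "SRS", "ADHD")
AF_DATASETS: tuple[str, ...] = (
    "gnomad_v2_exome_nonneuro",
    "gnomad_v2_genome_nonneuro",
    "gnomad_v3_nonneuro",
)
EXPR_DATASETS: tuple[str, ...] = ("gtex_brain", "brainspan", "hdbr")
PPI_DATABASES: tuple[str, ...] = ("consensuspathdb", "string", "giant")

MIRNA_SOURCES = ("mirna_seed", "mirna_mature", "mirna_loop")
UTR_SOURCES = ("utr_site_pass", "utr_site_fail_cs", "utr_site_fail_cons")
AF_STRATA = ("rare", "low", "common", "absent", "fail_qc")


@dataclass(frozen=True)
class PlantSpec:
    """One planted variant: inheritance mode, genomic stratum, phenotype,
    population-AF stratum, and whether its miRNA/gene is brain-expressed."""

    mode: str
    source: str
    phenotype: str
    af_stratum: str = "rare"
    expressed: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("dominant", "recessive", "de_novo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.source not in MIRNA_SOURCES + UTR_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.af_stratum not in AF_STRATA:
            raise ValueError(f"unknown af stratum {self.af_stratum!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


def default_plants() -> list[PlantSpec]:
    """Standard plant mix covering every mode, every genomic stratum, and
    every AF/expression failure stratum (22 plants)."""
    P = PlantSpec
    return [
        P("dominant", "mirna_seed", "RI"),
        P("dominant", "mirna_mature", "RI"),
        P("dominant", "mirna_mature", "LI"),
        P("recessive", "mirna_seed", "RI"),
        P("de_novo", "mirna_seed", "ASD"),
        P("dominant", "mirna_loop", "RI"),
        P("dominant", "mirna_seed", "SRS", expressed=False),
        P("dominant", "mirna_seed", "RI", af_stratum="common"),
        P("de_novo", "mirna_mature", "LI", af_stratum="low"),
        P("dominant", "mirna_seed", "ADHD", af_stratum="absent"),
        P("de_novo", "mirna_seed", "ASD", af_stratum="absent"),
        P("dominant", "mirna_mature", "RI", af_stratum="fail_qc"),
        P("dominant", "utr_site_pass", "RI"),
        P("dominant", "utr_site_pass", "SRS"),
        P("recessive", "utr_site_pass", "LI"),
        P("de_novo", "utr_site_pass", "ADHD"),
        P("dominant", "utr_site_fail_cs", "RI"),
        P("dominant", "utr_site_fail_cons", "LI"),
        P("dominant", "utr_site_pass", "RI", af_stratum="common"),
        P("de_novo", "utr_site_pass", "LI", af_stratum="low"),
        P("dominant", "utr_site_pass", "ADHD", expressed=False),
        P("recessive", "utr_site_pass", "RI", af_stratum="absent"),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Cohort and annotation layout; defaults emulate a 73-family /
    272-sample multi-phenotype cohort."""

    n_trio: int = 30
    n_quad: int = 33
    n_threegen: int = 10
    phenotypes: tuple[str, ...] = PHENOTYPES
    child_prevalence: dict = field(
        default_factory=lambda: {"ASD": 1.0, "LI": 0.4, "RI": 0.45, "SRS": 0.3, "ADHD": 0.25}
    )
    parent_prevalence: dict = field(
        default_factory=lambda: {"ASD": 0.0, "LI": 0.2, "RI": 0.2, "SRS": 0.15, "ADHD": 0.1}
    )
    plants: tuple[PlantSpec, ...] = field(default_factory=lambda: tuple(default_plants()))
    n_background_variants: int = 200
    af_strata_proportions: dict = field(
        default_factory=lambda: {"rare": 0.4, "low": 0.3, "common": 0.3}
    )
    af_qc_fail_fraction: float = 0.05
    missing_genotype_rate: float = 0.0
    n_mirnas: int = 40
    n_genes: int = 60
    n_decoy_x_variants: int = 1
    tpm_expressed_range: tuple[float, float] = (6.0, 60.0)
    tpm_silent_range: tuple[float, float] = (0.0, 4.0)
    rng_seed: int = 0

    @property
    def n_families(self) -> int:
        return self.n_trio + self.n_quad + self.n_threegen

    def validate(self) -> None:
        props = self.af_strata_proportions
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("af strata proportions must sum to 1")
        if len(self.plants) > self.n_families:
            raise ValueError("at most one plant per family: need more families")
        n_mirna_plants = sum(p.source in MIRNA_SOURCES for p in self.plants)
        n_utr_plants = sum(p.source in UTR_SOURCES for p in self.plants)
        if n_mirna_plants > self.n_mirnas:
            raise ValueError("more miRNA plants than synthetic miRNAs")
        if n_utr_plants > self.n_genes:
            raise ValueError("more 3'UTR plants than synthetic genes")
        for p in self.plants:
            if p.mode == "dominant" and self.parent_prevalence.get(p.phenotype, 0.0) == 0.0:
                raise ValueError(
                    f"infeasible plant: dominant inheritance for {p.phenotype} is "
                    f"impossible when no parent can be affected for {p.phenotype}"
                )


# ---------------------------------------------------------------------------
# layout constants (one synthetic chromosome)
# ---------------------------------------------------------------------------

_MIRNA_BASE = 10_000
_MIRNA_SPACING = 2_000
_HAIRPIN = 84
_BACKGROUND_LO = 1_000_000
_BACKGROUND_HI = 1_500_000
_UTR_BASE = 2_000_000
_UTR_SPACING = 5_000
_UTR_LEN = 1_000


def _hairpin_regions(start: int, strand: str) -> dict[str, tuple[int, int]]:
    """Region layout of one synthetic hairpin, 0-based half-open.

    arm1 | mature_a (22nt) | loop | mature_b (22nt) | arm2.  The seed is
    bases 2-8 of the mature counted 5'->3' on the miRNA strand, so on '-'
    it sits at the genomic end of the mature interval.
    """
    s = start
    mat_a = (s + 10, s + 32)
    mat_b = (s + 52, s + 74)
    if strand == "+":
        seed_a = (mat_a[0] + 1, mat_a[0] + 8)
        seed_b = (mat_b[0] + 1, mat_b[0] + 8)
    else:
        seed_a = (mat_a[1] - 8, mat_a[1] - 1)
        seed_b = (mat_b[1] - 8, mat_b[1] - 1)
    return {
        "arm1": (s, s + 10),
        "mature_a": mat_a,
        "seed_a": seed_a,
        "loop": (s + 32, s + 52),
        "mature_b": mat_b,
        "seed_b": seed_b,
        "arm2": (s + 74, s + 84),
    }


@dataclass
class SyntheticBundle:
    """Everything one simulation produced, in memory."""

    config: SimConfig
    pedigree: Pedigree
    variants: list[VariantRecord]
    truth: pd.DataFrame
    mirna_gff: str  # GFF3 text
    mirna_regions: pd.DataFrame  # internal (0-based) coordinates
    utr_regions: pd.DataFrame
    target_sites: pd.DataFrame
    af_table: pd.DataFrame
    expression: pd.DataFrame
    ppi: pd.DataFrame
    go: pd.DataFrame
    ndd_genes: list[str]


# ---------------------------------------------------------------------------
# pedigree construction
# ---------------------------------------------------------------------------

def _build_families(config: SimConfig) -> tuple[list[dict], list[str]]:
    """Family skeletons: member roles, parent links, founder order."""
    families = []
    idx = 0
    for kind, n in (("trio", config.n_trio), ("quad", config.n_quad), ("threegen", config.n_threegen)):
        for _ in range(n):
            idx += 1
            fam = f"FAM{idx:03d}"
            if kind == "trio":
                members = [
                    ("fa", None, None, "male"),
                    ("mo", None, None, "female"),
                    ("c1", "fa", "mo", "male"),
                ]
            elif kind == "quad":
                members = [
                    ("fa", None, None, "male"),
                    ("mo", None, None, "female"),
                    ("c1", "fa", "mo", "male"),
                    ("c2", "fa", "mo", "female"),
                ]
            else:
                members = [
                    ("gf", None, None, "male"),
                    ("gm", None, None, "female"),
                    ("fa", "gf", "gm", "male"),
                    ("mo", None, None, "female"),
                    ("c1", "fa", "mo", "male"),
                ]
            families.append({"family_id": fam, "kind": kind, "members": members})
    return families, [f["family_id"] for f in families]


#: roles whose members are children (probands) vs parental generation
_CHILD_ROLES = {"c1", "c2"}

# per-mode plant patterns: role -> (allele_count, affected_for_plant_phenotype)
_PLANT_PATTERNS: dict[tuple[str, str], dict[str, tuple[int, bool]]] = {
    ("dominant", "trio"): {"fa": (1, True), "mo": (0, False), "c1": (1, True)},
    ("dominant", "quad"): {"fa": (1, True), "mo": (0, False), "c1": (1, True), "c2": (0, False)},
    ("dominant", "threegen"): {
        "gf": (1, True), "gm": (0, False), "fa": (1, True), "mo": (0, False), "c1": (1, True),
    },
    ("recessive", "trio"): {"fa": (1, False), "mo": (1, False), "c1": (2, True)},
    ("recessive", "quad"): {"fa": (1, False), "mo": (1, False), "c1": (2, True), "c2": (1, False)},
    ("recessive", "threegen"): {
        "gf": (1, False), "gm": (0, False), "fa": (1, False), "mo": (1, False), "c1": (2, True),
    },
    ("de_novo", "trio"): {"fa": (0, False), "mo": (0, False), "c1": (1, True)},
    ("de_novo", "quad"): {"fa": (0, False), "mo": (0, False), "c1": (1, True), "c2": (0, False)},
    ("de_novo", "threegen"): {
        "gf": (0, False), "gm": (0, False), "fa": (0, False), "mo": (0, False), "c1": (1, True),
    },
}


def _assign_affection(
    config: SimConfig,
    families: list[dict],
    plant_family: dict[str, PlantSpec],
    rng: np.random.Generator,
) -> dict[str, dict[str, Affection]]:
    """Per-sample affection maps.

    Plant families carry exactly the plant pattern for the plant's
    phenotype and are unaffected for everything else; other families get
    random affection by role-specific prevalence, with the first child
    always an ASD proband.
    """
    affection: dict[str, dict[str, Affection]] = {}
    for fam in families:
        fid = fam["family_id"]
        plant = plant_family.get(fid)
        for role, _, _, _ in fam["members"]:
            sid = f"{fid}_{role}"
            aff: dict[str, Affection] = {}
            if plant is not None:
                pattern = _PLANT_PATTERNS[(plant.mode, fam["kind"])]
                for p in config.phenotypes:
                    if p == plant.phenotype:
                        aff[p] = (
                            Affection.AFFECTED if pattern[role][1] else Affection.UNAFFECTED
                        )
                    else:
                        aff[p] = Affection.UNAFFECTED
            else:
                is_child = role in _CHILD_ROLES
                for p in config.phenotypes:
                    prev = (
                        config.child_prevalence.get(p, 0.0)
                        if is_child
                        else config.parent_prevalence.get(p, 0.0)
                    )
                    if role == "c1" and p == "ASD":
                        aff[p] = Affection.AFFECTED
                    else:
                        aff[p] = (
                            Affection.AFFECTED if rng.random() < prev else Affection.UNAFFECTED
                        )
            affection[sid] = aff
    return affection


def _make_pedigree(config, families, affection) -> Pedigree:
    samples = []
    for fam in families:
        fid = fam["family_id"]
        for role, fa, mo, sex in fam["members"]:
            samples.append(
                Sample(
                    sample_id=f"{fid}_{role}",
                    family_id=fid,
                    father_id=f"{fid}_{fa}" if fa else None,
                    mother_id=f"{fid}_{mo}" if mo else None,
                    sex=sex,
                    affection=affection[f"{fid}_{role}"],
                )
            )
    return Pedigree(samples, list(config.phenotypes))


# ---------------------------------------------------------------------------
# genotype helpers
# ---------------------------------------------------------------------------

def _plant_genotypes(pedigree: Pedigree, fam: dict, plant: PlantSpec) -> dict[str, int | None]:
    pattern = _PLANT_PATTERNS[(plant.mode, fam["kind"])]
    fid = fam["family_id"]
    gts: dict[str, int | None] = {s: 0 for s in pedigree.sample_ids()}
    for role, (count, _) in pattern.items():
        gts[f"{fid}_{role}"] = count
    return gts


def _background_genotypes(
    pedigree: Pedigree, families: list[dict], af: float, rng: np.random.Generator,
    missing_rate: float,
) -> dict[str, int | None]:
    gts: dict[str, int | None] = {}
    for fam in families:
        fid = fam["family_id"]
        counts: dict[str, int] = {}
        for role, fa, mo, _ in fam["members"]:  # founders precede children
            if fa is None and mo is None:
                counts[role] = int(rng.binomial(2, af))
            else:
                t_fa = int(rng.random() < counts[fa] / 2.0)
                t_mo = int(rng.random() < counts[mo] / 2.0)
                counts[role] = t_fa + t_mo
        for role, _, _, _ in fam["members"]:
            sid = f"{fid}_{role}"
            gts[sid] = None if rng.random() < missing_rate else counts[role]
    return gts


# ---------------------------------------------------------------------------
# expected survival per funnel stage
# ---------------------------------------------------------------------------

def _af_expectation(plant: PlantSpec) -> bool:
    if plant.af_stratum == "common":
        return False
    if plant.af_stratum == "low":
        return plant.mode != "de_novo"
    return True  # rare; or absent/fail_qc, which fall back to private cohort AF


def _truth_row(plant: PlantSpec, variant: VariantRecord, family_id: str, extra: dict) -> dict:
    in_mirna = plant.source in MIRNA_SOURCES
    region_ok = plant.source in ("mirna_seed", "mirna_mature")
    site_ok = plant.source == "utr_site_pass"
    af_ok = _af_expectation(plant)
    row = {
        "chrom": variant.chrom,
        "pos": variant.pos,
        "ref": variant.ref,
        "alt": variant.alt,
        "variant_id": variant.variant_id,
        "family_id": family_id,
        "phenotype": plant.phenotype,
        "mode": plant.mode,
        "source": plant.source,
        "af_stratum": plant.af_stratum,
        "expressed": plant.expressed,
        "funnel": "mirna" if in_mirna else "utr",
        "expect_overlap": True,
        "expect_segregating": True,
        "expect_region": region_ok if in_mirna else site_ok,
        "expect_expressed": (region_ok if in_mirna else site_ok) and plant.expressed,
        "expect_af": (region_ok if in_mirna else site_ok) and plant.expressed and af_ok,
    }
    row["expect_final"] = row["expect_af"]
    row.update(extra)
    return row


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimConfig | None = None) -> SyntheticBundle:
    """Generate the full synthetic bundle for one configuration."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    families, family_ids = _build_families(config)
    by_fid = {f["family_id"]: f for f in families}

    # one plant per family, assigned in order
    plant_family: dict[str, PlantSpec] = {
        family_ids[i]: plant for i, plant in enumerate(config.plants)
    }
    affection = _assign_affection(config, families, plant_family, rng)
    pedigree = _make_pedigree(config, families, affection)

    # --- miRNA annotation layout -------------------------------------------
    mirna_rows = []  # internal coordinates
    gff_lines = ["##gff-version 3"]
    precursors = []
    for i in range(config.n_mirnas):
        start = _MIRNA_BASE + i * _MIRNA_SPACING
        strand = "+" if i % 2 == 0 else "-"
        name = f"hsa-mir-syn{i}"
        mat5, mat3 = f"hsa-miR-syn{i}-5p", f"hsa-miR-syn{i}-3p"
        regions = _hairpin_regions(start, strand)
        precursors.append(
            {"name": name, "chrom": "chr1", "start": start, "strand": strand,
             "mat5": mat5, "mat3": mat3, "regions": regions}
        )
        gff_lines.append(
            f"chr1\tsynthetic\tmiRNA_primary_transcript\t{start + 1}\t{start + _HAIRPIN}\t."
            f"\t{strand}\t.\tID=MI_SYN{i};Name={name}"
        )
        for mat_name, key in ((mat5, "mature_a"), (mat3, "mature_b")):
            a, b = regions[key]
            gff_lines.append(
                f"chr1\tsynthetic\tmiRNA\t{a + 1}\t{b}\t.\t{strand}\t."
                f"\tID=MIMAT_SYN{i}{key[-1]};Name={mat_name};Derives_from=MI_SYN{i}"
            )
        for label, key in (
            ("arm", "arm1"), ("mature", "mature_a"), ("seed", "seed_a"),
            ("loop", "loop"), ("mature", "mature_b"), ("seed", "seed_b"),
            ("arm", "arm2"),
        ):
            a, b = regions[key]
            mirna_rows.append(
                {"mirna_name": name, "region": label, "chrom": "chr1",
                 "start": a, "end": b, "strand": strand}
            )

    # one decoy hairpin on chrX for the autosomal-only rule
    x_regions = _hairpin_regions(_MIRNA_BASE, "+")
    gff_lines.append(
        f"chrX\tsynthetic\tmiRNA_primary_transcript\t{_MIRNA_BASE + 1}"
        f"\t{_MIRNA_BASE + _HAIRPIN}\t.\t+\t.\tID=MI_SYNX;Name=hsa-mir-synX"
    )
    for suffix, key in (("a", "mature_a"), ("b", "mature_b")):
        a, b = x_regions[key]
        arm = "5p" if suffix == "a" else "3p"
        gff_lines.append(
            f"chrX\tsynthetic\tmiRNA\t{a + 1}\t{b}\t.\t+\t."
            f"\tID=MIMAT_SYNX{suffix};Name=hsa-miR-synX-{arm};Derives_from=MI_SYNX"
        )
    for label, key in (
        ("arm", "arm1"), ("mature", "mature_a"), ("seed", "seed_a"),
        ("loop", "loop"), ("mature", "mature_b"), ("seed", "seed_b"), ("arm", "arm2"),
    ):
        a, b = x_regions[key]
        mirna_rows.append(
            {"mirna_name": "hsa-mir-synX", "region": label, "chrom": "chrX",
             "start": a, "end": b, "strand": "+"}
        )

    # --- gene / 3'UTR layout ------------------------------------------------
    utr_rows = []
    genes = []
    for j in range(config.n_genes):
        start = _UTR_BASE + j * _UTR_SPACING
        genes.append({"gene": f"GENE{j}", "start": start})
        utr_rows.append(
            {"gene": f"GENE{j}", "transcript": f"TX{j}", "chrom": "chr1",
             "start": start, "end": start + _UTR_LEN, "strand": "+"}
        )

    # --- variants -----------------------------------------------------------
    variants: list[VariantRecord] = []
    truth_rows: list[dict] = []
    site_rows = []  # internal coordinates
    af_rows = []
    expr_rows = []

    mirna_plant_idx = 0
    utr_plant_idx = 0
    expressed_mirna_plants: list[dict] = []  # for target-set construction
    plant_variant_ids = iter(f"rsSYN{k:04d}" for k in range(1, 10_000))

    def _af_rows_for(variant: VariantRecord, stratum: str) -> None:
        if stratum == "absent":
            return
        qc = stratum != "fail_qc"
        if stratum in ("rare", "fail_qc"):
            lo, hi = 1e-5, 9e-4
        elif stratum == "low":
            lo, hi = 1.1e-3, 9e-3
        else:  # common
            lo, hi = 2e-2, 5e-1
        present = list(AF_DATASETS)
        if rng.random() < 0.25:  # sometimes a dataset has no value
            present.remove(present[int(rng.integers(len(present)))])
        for ds in AF_DATASETS:
            af_rows.append(
                {
                    "chrom": variant.chrom,
                    "pos": variant.pos,
                    "ref": variant.ref,
                    "alt": variant.alt,
                    "dataset_id": ds,
                    "af": float(rng.uniform(lo, hi)) if ds in present else None,
                    "pass": qc,
                }
            )

    used_mirna_names: list[str] = []
    for i, plant in enumerate(config.plants):
        fid = family_ids[i]
        fam = by_fid[fid]
        if plant.source in MIRNA_SOURCES:
            prec = precursors[mirna_plant_idx]
            mirna_plant_idx += 1
            regions = prec["regions"]
            if plant.source == "mirna_seed":
                pos0 = regions["seed_a"][0]
            elif plant.source == "mirna_mature":
                # inside mature_a but outside its seed
                pos0 = regions["mature_a"][0] if prec["strand"] == "+" else regions["mature_a"][0]
            else:
                pos0 = regions["loop"][0] + 5
            chrom = "chr1"
            extra = {"mirna_name": prec["name"], "gene": ""}
            # mature-level brain expression for the hairpin's 5p product
            lo, hi = (
                config.tpm_expressed_range if plant.expressed else config.tpm_silent_range
            )
            for ds in EXPR_DATASETS:
                expr_rows.append(
                    {"feature_id": prec["mat5"], "dataset_id": ds,
                     "tpm": float(rng.uniform(lo, hi))}
                )
            if plant.expressed and plant.source in ("mirna_seed", "mirna_mature"):
                expressed_mirna_plants.append(prec)
            used_mirna_names.append(prec["name"])
        else:
            gene = genes[utr_plant_idx]
            utr_plant_idx += 1
            u = gene["start"]
            if plant.source == "utr_site_pass":
                cons, cs = "broadly_conserved", -0.6
            elif plant.source == "utr_site_fail_cs":
                cons, cs = "conserved", -0.2
            else:
                cons, cs = "poorly_conserved", -0.8
            fam_mirna = (
                expressed_mirna_plants[utr_plant_idx % len(expressed_mirna_plants)]["mat5"]
                if expressed_mirna_plants
                else "miR-synF0"
            )
            site_rows.append(
                {"gene": gene["gene"], "transcript": f"TX{gene['gene'][4:]}",
                 "chrom": "chr1", "utr_start": u + 100, "utr_end": u + 108,
                 "strand": "+", "mirna_family": fam_mirna,
                 "conservation_class": cons, "context_score": cs}
            )
            pos0 = u + 103
            chrom = "chr1"
            extra = {"mirna_name": "", "gene": gene["gene"]}
            lo, hi = (
                config.tpm_expressed_range if plant.expressed else config.tpm_silent_range
            )
            for ds in EXPR_DATASETS:
                expr_rows.append(
                    {"feature_id": gene["gene"], "dataset_id": ds,
                     "tpm": float(rng.uniform(lo, hi))}
                )
        variant = VariantRecord(
            chrom=chrom,
            pos=pos0 + 1,
            ref="A",
            alt="G",
            variant_id=next(plant_variant_ids),
            genotypes=_plant_genotypes(pedigree, fam, plant),
        )
        variants.append(variant)
        truth_rows.append(_truth_row(plant, variant, fid, extra))
        _af_rows_for(variant, plant.af_stratum)

    # chrX decoys: dominant-looking pattern inside the chrX hairpin seed
    if config.plants:
        mirror = config.plants[0]
        mirror_fid = family_ids[0]
        for k in range(config.n_decoy_x_variants):
            variant = VariantRecord(
                chrom="chrX",
                pos=x_regions["seed_a"][0] + 1 + k,
                ref="C",
                alt="T",
                variant_id=next(plant_variant_ids),
                genotypes=_plant_genotypes(pedigree, by_fid[mirror_fid], mirror),
            )
            variants.append(variant)
            truth_rows.append(
                _truth_row(
                    replace(mirror, af_stratum="rare"), variant, mirror_fid,
                    {"mirna_name": "hsa-mir-synX", "gene": ""},
                )
                | {
                    "expect_segregating": False, "expect_region": False,
                    "expect_expressed": False, "expect_af": False,
                    "expect_final": False, "source": "x_decoy", "funnel": "mirna",
                }
            )
            _af_rows_for(variant, "rare")

    # --- background variants (intergenic; never enter a funnel) -------------
    strata = list(config.af_strata_proportions)
    probs = np.array([config.af_strata_proportions[s] for s in strata])
    bg_positions = rng.choice(
        np.arange(_BACKGROUND_LO, _BACKGROUND_HI), size=config.n_background_variants,
        replace=False,
    )
    bg_positions.sort()
    for pos0 in bg_positions:
        stratum = strata[int(rng.choice(len(strata), p=probs))]
        af = {
            "rare": float(rng.uniform(1e-5, 9e-4)),
            "low": float(rng.uniform(1.1e-3, 9e-3)),
            "common": float(rng.uniform(2e-2, 5e-1)),
        }[stratum]
        variant = VariantRecord(
            chrom="chr1",
            pos=int(pos0) + 1,
            ref="T",
            alt="C",
            genotypes=_background_genotypes(
                pedigree, families, af, rng, config.missing_genotype_rate
            ),
        )
        variants.append(variant)
        for ds in AF_DATASETS:
            af_rows.append(
                {"chrom": variant.chrom, "pos": variant.pos, "ref": variant.ref,
                 "alt": variant.alt, "dataset_id": ds,
                 "af": min(1.0, max(0.0, float(af * rng.uniform(0.5, 1.5)))),
                 "pass": bool(rng.random() >= config.af_qc_fail_fraction)}
            )

    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))

    # --- extra target sites and expression for non-plant genes --------------
    # every expressed miRNA plant targets a handful of decoy genes so the
    # target-gene analysis has realistic content
    decoy_gene_start = utr_plant_idx
    for p_idx, prec in enumerate(expressed_mirna_plants):
        for k in range(4):
            g = genes[(decoy_gene_start + p_idx * 4 + k) % config.n_genes]
            site_rows.append(
                {"gene": g["gene"], "transcript": f"TX{g['gene'][4:]}",
                 "chrom": "chr1", "utr_start": g["start"] + 300 + 20 * k,
                 "utr_end": g["start"] + 308 + 20 * k, "strand": "+",
                 "mirna_family": prec["mat5"],
                 "conservation_class": "conserved" if k % 2 else "broadly_conserved",
                 "context_score": float(rng.uniform(-0.9, -0.45)) if k < 3 else float(rng.uniform(-0.35, -0.05))}
            )
    seen_expr = {r["feature_id"] for r in expr_rows}
    for g in genes:
        if g["gene"] in seen_expr:
            continue
        expressed = rng.random() < 0.6
        lo, hi = config.tpm_expressed_range if expressed else config.tpm_silent_range
        for ds in EXPR_DATASETS:
            expr_rows.append(
                {"feature_id": g["gene"], "dataset_id": ds, "tpm": float(rng.uniform(lo, hi))}
            )

    # --- PPI and GO ---------------------------------------------------------
    ndd_genes = [f"NDD{k}" for k in range(1, 11)]
    universe = [g["gene"] for g in genes] + ndd_genes
    ppi_rows = []
    n_base_edges = 80
    for _ in range(n_base_edges):
        a, b = rng.choice(len(universe), size=2, replace=False)
        pair = (universe[int(a)], universe[int(b)])
        dbs = [db for db in PPI_DATABASES if rng.random() < 0.6]
        if not dbs:
            dbs = [PPI_DATABASES[int(rng.integers(3))]]
        for db in dbs:
            ppi_rows.append({"gene_a": pair[0], "gene_b": pair[1], "source_db": db})
    # decoys: self-loops and duplicated rows
    for k in range(3):
        g = universe[int(rng.integers(len(universe)))]
        ppi_rows.append({"gene_a": g, "gene_b": g, "source_db": PPI_DATABASES[k % 3]})
    ppi_rows.extend(ppi_rows[:5])

    go_rows = []
    for t in range(15):
        size = int(rng.integers(4, 30))
        members = rng.choice(len(universe), size=size, replace=False)
        for m in members:
            go_rows.append(
                {"term_id": f"GO:SYN{t:04d}", "term_name": f"synthetic process {t}",
                 "gene": universe[int(m)]}
            )

    truth_columns = [
        "chrom", "pos", "ref", "alt", "variant_id", "family_id", "phenotype",
        "mode", "source", "af_stratum", "expressed", "funnel", "expect_overlap",
        "expect_segregating", "expect_region", "expect_expressed", "expect_af",
        "expect_final", "mirna_name", "gene",
    ]
    truth = pd.DataFrame(truth_rows, columns=truth_columns)
    site_columns = [
        "gene", "transcript", "chrom", "utr_start", "utr_end", "strand",
        "mirna_family", "conservation_class", "context_score",
    ]
    af_columns = ["chrom", "pos", "ref", "alt", "dataset_id", "af", "pass"]
    return SyntheticBundle(
        config=config,
        pedigree=pedigree,
        variants=variants,
        truth=truth,
        mirna_gff="\n".join(gff_lines) + "\n",
        mirna_regions=pd.DataFrame(mirna_rows),
        utr_regions=pd.DataFrame(utr_rows),
        target_sites=pd.DataFrame(site_rows, columns=site_columns),
        af_table=pd.DataFrame(af_rows, columns=af_columns),
        expression=pd.DataFrame(expr_rows),
        ppi=pd.DataFrame(ppi_rows),
        go=pd.DataFrame(go_rows),
        ndd_genes=ndd_genes,
    )


def simulate_cohort(config: SimConfig | None = None) -> tuple[Pedigree, list[VariantRecord], pd.DataFrame]:
    """Pedigree, variant list, and truth table for one configuration."""
    b = simulate_bundle(config)
    return b.pedigree, b.variants, b.truth


def simulate_annotations(config: SimConfig | None = None) -> dict:
    """Annotation-side tables only (same layout as the cohort with the
    same config/seed)."""
    b = simulate_bundle(config)
    return {
        "mirna_gff": b.mirna_gff,
        "mirna_regions": b.mirna_regions,
        "utr_regions": b.utr_regions,
        "target_sites": b.target_sites,
        "af": b.af_table,
        "expression": b.expression,
        "ppi": b.ppi,
        "go": b.go,
        "ndd_genes": b.ndd_genes,
    }


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_vcf(variants: list[VariantRecord], sample_ids: list[str], path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotypes."""
    _GT = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for v in variants:
            gts = "\t".join(_GT[v.genotypes.get(s)] for s in sample_ids)
            filt = "PASS" if v.qual_pass else "FAIL"
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t{filt}\t.\tGT\t{gts}\n"
            )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "ped": outdir / "cohort.ped",
        "mirna_gff": outdir / "mirna.gff3",
        "mirna_regions": outdir / "mirna_regions.tsv",
        "utr_regions": outdir / "utr_regions.tsv",
        "target_sites": outdir / "target_sites.tsv",
        "af": outdir / "population_af.tsv",
        "expression": outdir / "expression.tsv",
        "ppi": outdir / "ppi_edges.tsv",
        "go": outdir / "go_annotation.tsv",
        "ndd_genes": outdir / "ndd_genes.txt",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(bundle.variants, bundle.pedigree.sample_ids(), paths["vcf"])
    write_ped(bundle.pedigree, paths["ped"])
    paths["mirna_gff"].write_text(bundle.mirna_gff)
    write_interval_table(bundle.mirna_regions, paths["mirna_regions"], "mirna_regions")
    write_interval_table(bundle.utr_regions, paths["utr_regions"], "utr_regions")
    write_interval_table(bundle.target_sites, paths["target_sites"], "target_sites")
    af = bundle.af_table.copy()
    af["af"] = af["af"].map(lambda x: "" if x is None or pd.isna(x) else repr(float(x)))
    af["pass"] = af["pass"].map({True: "true", False: "false"})
    af.to_csv(paths["af"], sep="\t", index=False)
    bundle.expression.to_csv(paths["expression"], sep="\t", index=False)
    bundle.ppi.to_csv(paths["ppi"], sep="\t", index=False)
    bundle.go.to_csv(paths["go"], sep="\t", index=False)
    paths["ndd_genes"].write_text("\n".join(bundle.ndd_genes) + "\n")
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
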