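"""Readers, writers, and the internal data model for every external format.

All genomic intervals are held internally as 0-based half-open
``[start, end)`` on a named chromosome.  On-disk tabular formats follow the
usual bioinformatics conventions (VCF and GFF3 are 1-based inclusive; the
companion TSVs declared here carry 1-based inclusive ``start``/``end``
columns) and are converted at the I/O boundary, never downstream.

Variants are assumed normalized upstream (left-aligned, trimmed) by the
variant caller; no re-normalization is attempted here.  Multiallelic VCF
rows are decomposed into one biallelic record per alternate allele, with
per-sample allele counts recomputed against that single alternate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "Affection",
    "Sample",
    "Pedigree",
    "VariantRecord",
    "AfRecord",
    "ExpressionRecord",
    "StrandedInterval",
    "variant_key",
    "normalize_chrom",
    "read_vcf",
    "read_ped",
    "write_ped",
    "read_interval_table",
    "write_interval_table",
    "INTERVAL_TABLE_COLUMNS",
]

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "chrMT", "chrM"})


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Map a chromosome name onto the configured naming style.

    Only the ``"chr"``-prefixed style is supported; ``MT``/``chrM`` are
    folded to ``chrMT``.
    """
    if style != "chr":
        raise ValueError(f"unsupported chromosome naming style: {style!r}")
    base = name[3:] if name.startswith("chr") else name
    if base == "M":
        base = "MT"
    return "chr" + base


class Affection(enum.Enum):
    """Per-phenotype affection status of one pedigree member."""

    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


#: PED affection coding: 2=affected, 1=unaffected, 0/-9=unknown.
_PED_AFFECTION = {
    "2": Affection.AFFECTED,
    "1": Affection.UNAFFECTED,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
}
_PED_AFFECTION_OUT = {
    Affection.AFFECTED: "2",
    Affection.UNAFFECTED: "1",
    Affection.UNKNOWN: "0",
}


@dataclass(frozen=True)
class Sample:
    sample_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" / "female" / "unknown"
    affection: dict[str, Affection] = field(default_factory=dict, hash=False)

    def status(self, phenotype: str) -> Affection:
        try:
            return self.affection[phenotype]
        except KeyError:
            raise KeyError(f"unknown phenotype {phenotype!r} for sample {self.sample_id}")


class Pedigree:
    """A cohort of families with per-phenotype affection status.

    Validates on construction: unique sample ids, parent links resolving
    within the same family, and no sample being its own ancestor.
    """

    def __init__(self, samples: Sequence[Sample], phenotypes: Sequence[str]):
        self.samples: list[Sample] = list(samples)
        self.phenotypes: list[str] = list(phenotypes)
        self.by_id: dict[str, Sample] = {}
        for s in self.samples:
            if s.sample_id in self.by_id:
                raise ValueError(f"duplicate sample id: {s.sample_id}")
            self.by_id[s.sample_id] = s
        self.families: dict[str, list[Sample]] = {}
        for s in self.samples:
            self.families.setdefault(s.family_id, []).append(s)
        self._validate()

    def _validate(self) -> None:
        for s in self.samples:
            for pid in (s.father_id, s.mother_id):
                if pid is None:
                    continue
                parent = self.by_id.get(pid)
                if parent is None:
                    raise ValueError(f"sample {s.sample_id}: dangling parent id {pid}")
                if parent.family_id != s.family_id:
                    raise ValueError(
                        f"sample {s.sample_id}: parent {pid} is in family "
                        f"{parent.family_id}, not {s.family_id}"
                    )
            missing = [p for p in self.phenotypes if p not in s.affection]
            if missing:
                raise ValueError(f"sample {s.sample_id}: missing affection for {missing}")
        # ancestor cycle check by DFS over parent links
        for s in self.samples:
            seen = set()
            stack = [s.sample_id]
            while stack:
                sid = stack.pop()
                cur = self.by_id[sid]
                for pid in (cur.father_id, cur.mother_id):
                    if pid is None:
                        continue
                    if pid == s.sample_id:
                        raise ValueError(f"sample {s.sample_id} is its own ancestor")
                    if pid not in seen:
                        seen.add(pid)
                        stack.append(pid)

    def parents(self, sample: Sample) -> list[Sample]:
        return [self.by_id[p] for p in (sample.father_id, sample.mother_id) if p is not None]

    def affected(self, phenotype: str, family_id: str | None = None) -> list[Sample]:
        pool = self.families[family_id] if family_id is not None else self.samples
        return [s for s in pool if s.status(phenotype) is Affection.AFFECTED]

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def family_of(self, sample_id: str) -> str:
        return self.by_id[sample_id].family_id

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class VariantRecord:
    """One normalized biallelic variant with per-sample genotypes.

    ``genotypes`` maps sample id to the count of the (single) alternate
    allele: 0, 1, 2, or None for missing.  ``pos`` is the 1-based VCF
    position; the genomic footprint used for all overlap arithmetic is the
    0-based half-open interval ``[pos - 1, pos - 1 + len(ref))``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str = "."
    genotypes: dict[str, int | None] = field(default_factory=dict, hash=False)
    qual_pass: bool = True

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def start(self) -> int:
        return self.pos - 1

    @property
    def end(self) -> int:
        return self.pos - 1 + len(self.ref)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_autosomal(self) -> bool:
        return self.chrom not in SEX_CHROMOSOMES

    def carriers(self) -> list[str]:
        return [s for s, ac in self.genotypes.items() if ac is not None and ac > 0]


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    return (chrom, int(pos), ref, alt)


@dataclass(frozen=True)
class AfRecord:
    """Population alternate-allele frequency of one variant in one dataset.

    ``af`` is None when the dataset reports no frequency; ``qc_pass`` is
    False when the variant failed the reference database's quality-control
    filters, in which case the frequency is not used.
    """

    key: tuple[str, int, str, str]
    dataset_id: str
    af: float | None
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError(f"af out of [0,1]: {self.af}")


@dataclass(frozen=True)
class ExpressionRecord:
    feature_id: str
    dataset_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"tpm must be non-negative: {self.tpm}")


@dataclass(frozen=True)
class StrandedInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -: {self.strand}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def contains(self, other: "StrandedInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    sample_subset: Sequence[str] | None = None,
    chrom_style: str = "chr",
) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF 4.x file with GT genotypes.

    Multiallelic rows are decomposed into one record per alternate allele;
    each sample's allele count for a record is the number of times that
    record's alternate appears in the sample's genotype.  Any genotype
    containing a missing allele yields ``None``.  Records whose FILTER
    field is neither PASS nor '.' are flagged ``qual_pass=False`` but still
    emitted.
    """
    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    if sample_subset is not None:
        absent = [s for s in sample_subset if s not in header_samples]
        if absent:
            raise ValueError(f"samples not in VCF header: {absent}")
        keep_idx = [(i, s) for i, s in enumerate(header_samples) if s in set(sample_subset)]
    else:
        keep_idx = list(enumerate(header_samples))

    for v in vcf:
        alts = v.ALT or []
        gts = v.genotypes  # per sample: [allele0, allele1, ..., phased]
        for alt_index, alt in enumerate(alts, start=1):
            genotypes: dict[str, int | None] = {}
            for i, sample_id in keep_idx:
                alleles = gts[i][:-1]
                if any(a < 0 for a in alleles):
                    genotypes[sample_id] = None
                else:
                    genotypes[sample_id] = sum(1 for a in alleles if a == alt_index)
            yield VariantRecord(
                chrom=normalize_chrom(v.CHROM, chrom_style),
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                variant_id=v.ID or ".",
                genotypes=genotypes,
                qual_pass=v.FILTER is None,  # cyvcf2: None means PASS or '.'
            )


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX = {"1": "male", "2": "female", "0": "unknown"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


def read_ped(path: str | Path, phenotype_columns: Sequence[str]) -> Pedigree:
    """Read a PED-style whitespace table with one affection column per phenotype.

    Columns: family, sample, father, mother, sex, then one column per entry
    of ``phenotype_columns`` (the standard 6th PED column being the first).
    Affection coding follows PED: 2=affected, 1=unaffected, 0 or -9=unknown.
    """
    phenotypes = list(phenotype_columns)
    n_expected = 5 + len(phenotypes)
    samples: list[Sample] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != n_expected:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_expected} columns, got {len(fields)}"
                )
            fam, sid, father, mother, sex = fields[:5]
            affection = {}
            for pheno, code in zip(phenotypes, fields[5:]):
                try:
                    affection[pheno] = _PED_AFFECTION[code]
                except KeyError:
                    raise ValueError(f"{path}:{lineno}: bad affection code {code!r}")
            samples.append(
                Sample(
                    sample_id=sid,
                    family_id=fam,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX.get(sex, "unknown"),
                    affection=affection,
                )
            )
    return Pedigree(samples, phenotypes)


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in pedigree.samples:
            row = [
                s.family_id,
                s.sample_id,
                s.father_id or "0",
                s.mother_id or "0",
                _SEX_OUT[s.sex],
            ] + [_PED_AFFECTION_OUT[s.affection[p]] for p in pedigree.phenotypes]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Interval / annotation tables
# ---------------------------------------------------------------------------

#: Required columns per table kind.  ``start``/``end`` columns are 1-based
#: inclusive on disk and converted to 0-based half-open on read.
INTERVAL_TABLE_COLUMNS: dict[str, list[str]] = {
    "mirna_regions": ["mirna_name", "region", "chrom", "start", "end", "strand"],
    "utr_regions": ["gene", "transcript", "chrom", "start", "end", "strand"],
    "target_sites": [
        "gene",
        "transcript",
        "chrom",
        "utr_start",
        "utr_end",
        "strand",
        "mirna_family",
        "conservation_class",
        "context_score",
    ],
    "af": ["chrom", "pos", "ref", "alt", "dataset_id", "af", "pass"],
    "expression": ["feature_id", "dataset_id", "tpm"],
    "ppi": ["gene_a", "gene_b", "source_db"],
    "go": ["term_id", "term_name", "gene"],
}

_COORD_COLUMNS = {
    "mirna_regions": ("start", "end"),
    "utr_regions": ("start", "end"),
    "target_sites": ("utr_start", "utr_end"),
}


def read_interval_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one of the pipeline's TSV side tables, validated and normalized.

    Returns a DataFrame with the kind's required columns; interval
    coordinates are converted to the internal 0-based half-open convention.
    Rows failing validation (non-numeric coordinates, AF outside [0,1],
    negative TPM, unknown conservation class) are dropped and counted in
    ``df.attrs['n_rejected']``.
    """
    if kind not in INTERVAL_TABLE_COLUMNS:
        raise ValueError(f"unknown interval table kind: {kind!r}")
    required = INTERVAL_TABLE_COLUMNS[kind]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns for {kind}: {missing}")
    df = df[required].copy()
    n_in = len(df)

    def _numeric(col: str, allow_missing: bool = False) -> None:
        vals = pd.to_numeric(df[col].replace("", None), errors="coerce")
        if not allow_missing:
            df.drop(index=df.index[vals.isna()], inplace=True)
        df[col] = vals.loc[df.index]

    if kind in _COORD_COLUMNS:
        c0, c1 = _COORD_COLUMNS[kind]
        _numeric(c0)
        _numeric(c1)
        df[c0] = df[c0].astype(int) - 1  # 1-based inclusive -> 0-based half-open
        df[c1] = df[c1].astype(int)
        df.drop(index=df.index[df[c1] <= df[c0]], inplace=True)
        df["chrom"] = df["chrom"].map(normalize_chrom)
        bad_strand = df.index[~df["strand"].isin(["+", "-"])]
        df.drop(index=bad_strand, inplace=True)
    if kind == "mirna_regions":
        df.drop(index=df.index[~df["region"].isin(["seed", "mature", "loop", "arm"])], inplace=True)
    if kind == "target_sites":
        _numeric("context_score")
        ok = df["conservation_class"].isin(
            ["broadly_conserved", "conserved", "poorly_conserved"]
        )
        df.drop(index=df.index[~ok], inplace=True)
    if kind == "af":
        df["chrom"] = df["chrom"].map(normalize_chrom)
        _numeric("pos")
        df["pos"] = df["pos"].astype(int)
        _numeric("af", allow_missing=True)
        bad = df.index[df["af"].notna() & ~df["af"].between(0.0, 1.0)]
        df.drop(index=bad, inplace=True)
        df["pass"] = df["pass"].str.lower().isin(["true", "1", "pass", "yes"])
    if kind == "expression":
        _numeric("tpm")
        df.drop(index=df.index[df["tpm"] < 0], inplace=True)

    df.reset_index(drop=True, inplace=True)
    df.attrs["n_rejected"] = n_in - len(df)
    df.attrs["kind"] = kind
    return df


def write_interval_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a side table back to TSV, undoing the coordinate normalization."""
    if kind not in INTERVAL_TABLE_COLUMNS:
        raise ValueError(f"unknown interval table kind: {kind!r}")
    out = df[INTERVAL_TABLE_COLUMNS[kind]].copy()
    if kind in _COORD_COLUMNS:
        c0, _ = _COORD_COLUMNS[kind]
        out[c0] = out[c0].astype(int) + 1
    if kind == "af":
        out["pass"] = out["pass"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)


def af_records_from_table(df: pd.DataFrame) -> dict[tuple[str, int, str, str], list[AfRecord]]:
    """Group an AF table into per-variant AfRecord lists (QC-failed rows kept,
    flagged; the filter layer decides how to treat them)."""
    out: dict[tuple[str, int, str, str], list[AfRecord]] = {}
    for row in df.to_dict(orient="records"):
        key = variant_key(row["chrom"], row["pos"], row["ref"], row["alt"])
        af = None if pd.isna(row["af"]) else float(row["af"])
        rec = AfRecord(key=key, dataset_id=row["dataset_id"], af=af, qc_pass=bool(row["pass"]))
        out.setdefault(key, []).append(rec)
    return out


def expression_records_from_table(df: pd.DataFrame) -> dict[str, list[ExpressionRecord]]:
    out: dict[str, list[ExpressionRecord]] = {}
    for row in df.itertuples(index=False):
        rec = ExpressionRecord(feature_id=row.feature_id, dataset_id=row.dataset_id, tpm=float(row.tpm))
        out.setdefault(rec.feature_id, []).append(rec)
    return out
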