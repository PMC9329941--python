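"""Classify variants by overlap with miRNA hairpins and functional regions.

A precursor (hairpin) miRNA is annotated with its mature strand(s) and the
functional sub-regions of the hairpin: the seed (bases 2-8 of a mature
miRNA, counted 5'->3' on the miRNA strand), the remainder of each mature
miRNA, the loop, and the arms.  A variant overlapping a hairpin is assigned
the most specific region any base of its reference footprint touches, with
precedence seed > mature > loop > arm.  Insertions occupy their single VCF
anchor base.

Region intervals come from a companion TSV rather than being re-derived
from sequence: hairpin secondary structure is not modelled here, so
arm/loop boundaries are whatever the annotation source provides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from intervaltree import IntervalTree

from .io_formats import StrandedInterval, VariantRecord, normalize_chrom, read_interval_table

__all__ = [
    "MirnaAnnotation",
    "RegionCall",
    "RegionIndex",
    "REGION_PRECEDENCE",
    "read_mirna_annotations",
    "build_region_index",
    "classify_variant",
]

#: Most specific first.
REGION_PRECEDENCE: tuple[str, ...] = ("seed", "mature", "loop", "arm")
_RANK = {r: i for i, r in enumerate(REGION_PRECEDENCE)}


@dataclass
class MirnaAnnotation:
    """One precursor miRNA with its mature products and region intervals."""

    mirna_name: str
    precursor_interval: StrandedInterval
    mature_names: list[str] = field(default_factory=list)
    mature_intervals: dict[str, StrandedInterval] = field(default_factory=dict)
    region_intervals: list[tuple[str, StrandedInterval]] = field(default_factory=list)

    def validate(self) -> None:
        strand = self.precursor_interval.strand
        for label, iv in self.region_intervals:
            if label not in _RANK:
                raise ValueError(f"{self.mirna_name}: unknown region label {label!r}")
            if iv.strand != strand:
                raise ValueError(f"{self.mirna_name}: region strand differs from precursor")
            if not self.precursor_interval.contains(iv):
                raise ValueError(
                    f"{self.mirna_name}: {label} interval [{iv.start},{iv.end}) "
                    f"outside precursor"
                )
        matures = [iv for lab, iv in self.region_intervals if lab == "mature"]
        matures += list(self.mature_intervals.values())
        for label, iv in self.region_intervals:
            if label == "seed" and not any(m.contains(iv) for m in matures):
                raise ValueError(f"{self.mirna_name}: seed interval not inside any mature")

    def mature_name_at(self, start: int, end: int) -> str | None:
        for name, iv in self.mature_intervals.items():
            if iv.overlaps(start, end):
                return name
        return None


@dataclass(frozen=True)
class RegionCall:
    """The most specific miRNA region overlapped by one variant."""

    variant_key: tuple[str, int, str, str]
    mirna_name: str
    region: str
    mature_name: str | None = None


def read_mirna_annotations(gff_path: str | Path, regions_path: str | Path) -> list[MirnaAnnotation]:
    """Load precursor/mature structure from a miRBase-style GFF3 plus a
    companion region TSV (columns: mirna_name, region, chrom, start, end,
    strand; 1-based inclusive on disk).

    GFF3 features used: ``miRNA_primary_transcript`` (precursors) and
    ``miRNA`` (mature products, linked to their precursor by Derives_from
    or by containment).
    """
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    annotations: dict[str, MirnaAnnotation] = {}
    id_to_name: dict[str, str] = {}
    for feat in db.features_of_type("miRNA_primary_transcript"):
        name = feat.attributes.get("Name", [feat.id])[0]
        iv = StrandedInterval(normalize_chrom(feat.seqid), feat.start - 1, feat.end, feat.strand)
        annotations[name] = MirnaAnnotation(mirna_name=name, precursor_interval=iv)
        id_to_name[feat.id] = name
    for feat in db.features_of_type("miRNA"):
        name = feat.attributes.get("Name", [feat.id])[0]
        iv = StrandedInterval(normalize_chrom(feat.seqid), feat.start - 1, feat.end, feat.strand)
        parent = feat.attributes.get("Derives_from", [None])[0]
        owner = None
        if parent is not None and parent in id_to_name:
            owner = annotations[id_to_name[parent]]
        else:
            for ann in annotations.values():
                if ann.precursor_interval.contains(iv):
                    owner = ann
                    break
        if owner is None:
            raise ValueError(f"mature miRNA {name} has no containing precursor")
        owner.mature_names.append(name)
        owner.mature_intervals[name] = iv

    regions = read_interval_table(regions_path, "mirna_regions")
    for row in regions.itertuples(index=False):
        if row.mirna_name not in annotations:
            raise ValueError(f"region row references unknown precursor {row.mirna_name}")
        ann = annotations[row.mirna_name]
        ann.region_intervals.append(
            (row.region, StrandedInterval(row.chrom, row.start, row.end, row.strand))
        )
    out = list(annotations.values())
    for ann in out:
        ann.validate()
    return out


class RegionIndex:
    """Interval index over precursor miRNAs supporting stabbing queries."""

    def __init__(self, annotations: list[MirnaAnnotation]):
        for ann in annotations:
            ann.validate()
        self.annotations = annotations
        self._trees: dict[str, IntervalTree] = {}
        for ann in annotations:
            iv = ann.precursor_interval
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, ann)

    @property
    def n_precursors(self) -> int:
        return len(self.annotations)

    def query(self, chrom: str, start: int, end: int) -> list[MirnaAnnotation]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        return sorted(hits, key=lambda a: (a.precursor_interval.start, a.mirna_name))


def build_region_index(annotations: list[MirnaAnnotation]) -> RegionIndex:
    return RegionIndex(annotations)


def classify_variant(variant: VariantRecord, index: RegionIndex) -> list[RegionCall]:
    """Assign each overlapped precursor's most specific region to a variant.

    One RegionCall per overlapped precursor whose region intervals the
    variant footprint touches; precedence seed > mature > loop > arm.  A
    variant overlapping no precursor (or only unannotated hairpin bases)
    yields an empty list.
    """
    start, end = variant.start, variant.end
    calls: list[RegionCall] = []
    for ann in index.query(variant.chrom, start, end):
        overlapped = [
            (label, iv)
            for label, iv in ann.region_intervals
            if iv.chrom == variant.chrom and iv.overlaps(start, end)
        ]
        if not overlapped:
            continue
        label, iv = min(overlapped, key=lambda t: _RANK[t[0]])
        mature_name = None
        if label in ("seed", "mature"):
            mature_name = ann.mature_name_at(iv.start, iv.end) or ann.mature_name_at(start, end)
        calls.append(
            RegionCall(
                variant_key=variant.key,
                mirna_name=ann.mirna_name,
                region=label,
                mature_name=mature_name,
            )
        )
    return calls
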