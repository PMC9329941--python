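"""Population allele-frequency and brain-expression filters, plus the
candidate-miRNA funnel that chains them.

Rare-variant selection uses mode-specific allele-frequency (AF) cutoffs
against reference population datasets (three gnomAD-style non-neuro
tables by default): AF < 1% for dominant and recessive calls and
AF < 0.1% for de novo calls, required in *every* dataset where the
variant is reported.  Records the reference database flagged as failing
its own quality control are ignored.  Variants absent from all reference
datasets fall back to the cohort itself: dominant/recessive pass when the
cohort alternate-allele frequency is below 1%; de novo passes only when
the alternate allele is absent from every sample outside the candidate's
family.

Brain expression uses a transcripts-per-million (TPM) rule: a feature
counts as brain-expressed when any expression dataset reports TPM
strictly greater than the cutoff (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import AfRecord, ExpressionRecord, Pedigree, VariantRecord
from .mirna_annotation import RegionCall
from .segregation import SegregationCall

__all__ = [
    "AfThresholds",
    "CohortAf",
    "passes_af_filter",
    "is_brain_expressed",
    "mirna_expression_lookup",
    "MirnaCandidate",
    "apply_mirna_cascade",
]


@dataclass(frozen=True)
class AfThresholds:
    """Mode-specific population AF cutoffs (strict inequality)."""

    dominant_recessive_max: float = 0.01
    de_novo_max: float = 0.001

    def __post_init__(self) -> None:
        if not (0.0 < self.de_novo_max <= self.dominant_recessive_max < 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < de_novo_max <= dominant_recessive_max < 1"
            )

    def for_mode(self, mode: str) -> float:
        if mode in ("dominant", "recessive"):
            return self.dominant_recessive_max
        if mode == "de_novo":
            return self.de_novo_max
        raise ValueError(f"unknown inheritance mode: {mode!r}")


class CohortAf:
    """Cohort-internal alternate-allele frequencies and carrier sets.

    The denominator is twice the number of samples with a non-missing
    genotype at the site, over all sequenced samples (relatedness is
    ignored for this fallback).
    """

    def __init__(self, variants, pedigree: Pedigree):
        self._freq: dict[tuple, float] = {}
        self._carriers: dict[tuple, frozenset[str]] = {}
        self._pedigree = pedigree
        for v in variants:
            self.add(v)

    def add(self, variant: VariantRecord) -> None:
        called = {s: g for s, g in variant.genotypes.items() if g is not None}
        n_alleles = 2 * len(called)
        n_alt = sum(called.values())
        self._freq[variant.key] = (n_alt / n_alleles) if n_alleles else 0.0
        self._carriers[variant.key] = frozenset(s for s, g in called.items() if g > 0)

    def frequency(self, key: tuple) -> float:
        return self._freq[key]

    def carriers_outside_family(self, key: tuple, family_id: str) -> frozenset[str]:
        return frozenset(
            s for s in self._carriers[key] if self._pedigree.family_of(s) != family_id
        )


def passes_af_filter(
    variant_key: tuple,
    mode: str,
    af_records: list[AfRecord],
    cohort_af: CohortAf | None,
    thresholds: AfThresholds = AfThresholds(),
    family_id: str | None = None,
) -> tuple[bool, str]:
    """Mode-specific rare-variant test; returns (passed, reason).

    Reference records failing the reference database's QC are discarded
    before the test.  With at least one usable AF value, the variant must
    be below the mode's cutoff in every dataset where it is reported.
    With none, the cohort fallback applies (see module docstring); the
    fallback requires ``cohort_af``, and the de novo fallback additionally
    requires ``family_id``.
    """
    cutoff = thresholds.for_mode(mode)
    usable = [r.af for r in af_records if r.qc_pass and r.af is not None]
    if usable:
        worst = max(usable)
        if worst < cutoff:
            return True, f"max reference AF {worst:.3g} < {cutoff:g} in all {len(usable)} datasets"
        return False, f"reference AF {worst:.3g} >= {cutoff:g} in at least one dataset"
    if cohort_af is None:
        raise ValueError("variant absent from reference datasets and no cohort AF supplied")
    if mode in ("dominant", "recessive"):
        f = cohort_af.frequency(variant_key)
        if f < thresholds.dominant_recessive_max:
            return True, f"absent from references; cohort AF {f:.3g} < {thresholds.dominant_recessive_max:g}"
        return False, f"absent from references; cohort AF {f:.3g} >= {thresholds.dominant_recessive_max:g}"
    # de novo: the alternate allele must be private to the candidate family
    if family_id is None:
        raise ValueError("de novo cohort fallback requires the candidate family id")
    outside = cohort_af.carriers_outside_family(variant_key, family_id)
    if outside:
        return False, f"absent from references; alt present in {len(outside)} sample(s) outside {family_id}"
    return True, f"absent from references; alt private to family {family_id}"


def is_brain_expressed(
    feature_id: str,
    expression_records: dict[str, list[ExpressionRecord]],
    tpm_min: float = 5.0,
) -> bool:
    """True iff any dataset reports TPM strictly greater than ``tpm_min``.

    A feature with no expression records is treated as not expressed.
    """
    return any(r.tpm > tpm_min for r in expression_records.get(feature_id, ()))


def mirna_expression_lookup(
    expression_records: dict[str, list[ExpressionRecord]],
) -> "_MirnaExpression":
    return _MirnaExpression(expression_records)


class _MirnaExpression:
    """Case-insensitive miRNA expression lookup: mature name first, then
    precursor name as fallback (expression tables may report either)."""

    def __init__(self, records: dict[str, list[ExpressionRecord]]):
        self._by_lower: dict[str, list[ExpressionRecord]] = {}
        for feat, recs in records.items():
            self._by_lower.setdefault(feat.lower(), []).extend(recs)

    def expressed(
        self, mature_name: str | None, precursor_name: str, tpm_min: float = 5.0
    ) -> bool:
        for name in (mature_name, precursor_name):
            if name is None:
                continue
            recs = self._by_lower.get(name.lower())
            if recs and any(r.tpm > tpm_min for r in recs):
                return True
        return False


@dataclass(frozen=True)
class MirnaCandidate:
    """A miRNA variant surviving the full candidate cascade for one
    (family, phenotype, mode) segregation context."""

    variant_key: tuple
    mirna_name: str
    mature_name: str | None
    region: str
    family_id: str
    phenotype: str
    mode: str
    af_reason: str = ""


def apply_mirna_cascade(
    region_calls: list[RegionCall],
    segregation_calls: list[SegregationCall],
    expression_records: dict[str, list[ExpressionRecord]],
    af_by_variant: dict[tuple, list[AfRecord]],
    thresholds: AfThresholds = AfThresholds(),
    cohort_af: CohortAf | None = None,
    tpm_min: float = 5.0,
    keep_regions: tuple[str, ...] = ("seed", "mature"),
) -> tuple[list[MirnaCandidate], dict[str, int]]:
    """Chain the miRNA-variant filters and report the funnel.

    Starting from variants with a miRNA region annotation, keep those
    that (1) segregate in some family/phenotype/mode, (2) lie in a
    functionally critical region (seed or mature by default), (3) fall in
    a brain-expressed miRNA, and (4) pass the mode-specific AF filter.
    Each filter is a pure predicate, so the surviving set is independent
    of stage order; the stage counts (unique variants) form the reported
    funnel.
    """
    funnel: dict[str, int] = {}
    region_by_variant: dict[tuple, list[RegionCall]] = {}
    for rc in region_calls:
        region_by_variant.setdefault(rc.variant_key, []).append(rc)
    funnel["mirna_overlap"] = len(region_by_variant)

    seg_by_variant: dict[tuple, list[SegregationCall]] = {}
    for sc in segregation_calls:
        if sc.variant_key in region_by_variant:
            seg_by_variant.setdefault(sc.variant_key, []).append(sc)
    funnel["segregating"] = len(seg_by_variant)

    expr = mirna_expression_lookup(expression_records)

    stage_region: set[tuple] = set()
    stage_expressed: set[tuple] = set()
    stage_af: set[tuple] = set()
    candidates: list[MirnaCandidate] = []
    for vkey, segs in seg_by_variant.items():
        rcs = [rc for rc in region_by_variant[vkey] if rc.region in keep_regions]
        if not rcs:
            continue
        stage_region.add(vkey)
        rcs_expr = [rc for rc in rcs if expr.expressed(rc.mature_name, rc.mirna_name, tpm_min)]
        if not rcs_expr:
            continue
        stage_expressed.add(vkey)
        for sc in segs:
            passed, reason = passes_af_filter(
                vkey, sc.mode, af_by_variant.get(vkey, []), cohort_af,
                thresholds, family_id=sc.family_id,
            )
            if not passed:
                continue
            stage_af.add(vkey)
            for rc in rcs_expr:
                candidates.append(
                    MirnaCandidate(
                        variant_key=vkey,
                        mirna_name=rc.mirna_name,
                        mature_name=rc.mature_name,
                        region=rc.region,
                        family_id=sc.family_id,
                        phenotype=sc.phenotype,
                        mode=sc.mode,
                        af_reason=reason,
                    )
                )
    funnel["seed_mature"] = len(stage_region)
    funnel["brain_expressed"] = len(stage_expressed)
    funnel["af_pass"] = len(stage_af)
    return candidates, funnel
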