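"""Strict Mendelian segregation engine for family cohorts.

Classifies variants as autosomal dominant, autosomal recessive, or de novo
per phenotype and per family, following strict family-based inheritance
semantics: a full trio (an affected proband with both parents genotyped)
is required, every individual whose genotype enters a predicate must have
non-missing data, and any unaffected carrier (for the mode's definition of
"carrier") vetoes the call.  Individuals whose affection status for the
phenotype is unknown are ignored by the carrier predicates — they neither
support nor veto a call — but a parent of an examined proband must still
satisfy the parental genotype requirement regardless of affection.

Mode predicates, evaluated within one family for one phenotype:

dominant
    Every affected is heterozygous; no unaffected carries the alternate
    allele; at least one affected child has an affected heterozygous
    parent (transmission is checked over every affected parent - affected
    child edge; one satisfied edge suffices).  Homozygous-alternate
    affecteds fail the heterozygosity requirement (configurable).

recessive
    Every affected is homozygous-alternate; every genotyped parent of an
    affected is a heterozygous carrier; no unaffected is
    homozygous-alternate.

de novo
    Every affected is heterozygous; every unaffected is homozygous
    reference; every parent of an affected that is present in the
    pedigree is homozygous reference.  The parental rule makes dominant
    and de novo mutually exclusive: dominant requires a carrier parent of
    an affected, which de novo forbids.

Sex chromosomes (X, Y, MT) are excluded from all modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import Affection, Pedigree, Sample, VariantRecord

__all__ = [
    "MODES",
    "SegregationCall",
    "family_has_full_trio",
    "check_dominant",
    "check_recessive",
    "check_de_novo",
    "check_mode",
    "scan_cohort",
]

MODES: tuple[str, ...] = ("dominant", "recessive", "de_novo")


@dataclass(frozen=True)
class SegregationCall:
    variant_key: tuple[str, int, str, str]
    family_id: str
    phenotype: str
    mode: str
    carrier_samples: tuple[str, ...]


def family_has_full_trio(pedigree: Pedigree, family_id: str, phenotype: str) -> bool:
    """True iff some member affected for ``phenotype`` has both parents in
    the pedigree (the full-trio eligibility requirement)."""
    if phenotype not in pedigree.phenotypes:
        raise ValueError(f"unknown phenotype: {phenotype!r}")
    for s in pedigree.families[family_id]:
        if s.status(phenotype) is Affection.AFFECTED:
            if s.father_id is not None and s.mother_id is not None:
                return True
    return False


def _gt(variant: VariantRecord, sample_id: str) -> int | None:
    return variant.genotypes.get(sample_id)


def _split_by_status(members: Sequence[Sample], phenotype: str):
    affected = [s for s in members if s.status(phenotype) is Affection.AFFECTED]
    unaffected = [s for s in members if s.status(phenotype) is Affection.UNAFFECTED]
    return affected, unaffected


def _call(variant, family_id, phenotype, mode, members) -> SegregationCall:
    carriers = tuple(
        s.sample_id
        for s in members
        if (g := _gt(variant, s.sample_id)) is not None and g > 0
    )
    return SegregationCall(
        variant_key=variant.key,
        family_id=family_id,
        phenotype=phenotype,
        mode=mode,
        carrier_samples=carriers,
    )


def check_dominant(
    variant: VariantRecord,
    pedigree: Pedigree,
    family_id: str,
    phenotype: str,
    allow_hom_alt_affected: bool = False,
) -> SegregationCall | None:
    """Strict autosomal-dominant test for one variant in one family."""
    if not variant.is_autosomal:
        return None
    if not family_has_full_trio(pedigree, family_id, phenotype):
        return None
    members = pedigree.families[family_id]
    affected, unaffected = _split_by_status(members, phenotype)
    if not affected:
        return None
    ok_affected = {1, 2} if allow_hom_alt_affected else {1}
    for s in affected:
        g = _gt(variant, s.sample_id)
        if g is None or g not in ok_affected:
            return None
    for s in unaffected:
        g = _gt(variant, s.sample_id)
        if g is None or g > 0:
            return None
    # transmission: at least one affected child with an affected carrier parent
    for child in affected:
        for parent in pedigree.parents(child):
            if parent.status(phenotype) is Affection.AFFECTED:
                g = _gt(variant, parent.sample_id)
                if g is not None and g >= 1:
                    return _call(variant, family_id, phenotype, "dominant", members)
    return None


def check_recessive(
    variant: VariantRecord,
    pedigree: Pedigree,
    family_id: str,
    phenotype: str,
) -> SegregationCall | None:
    """Strict autosomal-recessive test for one variant in one family."""
    if not variant.is_autosomal:
        return None
    if not family_has_full_trio(pedigree, family_id, phenotype):
        return None
    members = pedigree.families[family_id]
    affected, unaffected = _split_by_status(members, phenotype)
    if not affected:
        return None
    for s in affected:
        g = _gt(variant, s.sample_id)
        if g != 2:
            return None
        for parent in pedigree.parents(s):
            if _gt(variant, parent.sample_id) != 1:
                return None
    for s in unaffected:
        g = _gt(variant, s.sample_id)
        if g is None or g == 2:
            return None
    return _call(variant, family_id, phenotype, "recessive", members)


def check_de_novo(
    variant: VariantRecord,
    pedigree: Pedigree,
    family_id: str,
    phenotype: str,
) -> SegregationCall | None:
    """Strict de novo test for one variant in one family.

    Requires at least one affected proband with both parents genotyped
    homozygous reference; every affected heterozygous; every unaffected
    homozygous reference; no genotyped parent of any affected carries the
    alternate allele.
    """
    if not variant.is_autosomal:
        return None
    if not family_has_full_trio(pedigree, family_id, phenotype):
        return None
    members = pedigree.families[family_id]
    affected, unaffected = _split_by_status(members, phenotype)
    if not affected:
        return None
    for s in affected:
        if _gt(variant, s.sample_id) != 1:
            return None
        for parent in pedigree.parents(s):
            if _gt(variant, parent.sample_id) != 0:
                return None
    for s in unaffected:
        if _gt(variant, s.sample_id) != 0:
            return None
    # at least one affected has BOTH parents present (and thus hom-ref)
    for s in affected:
        if s.father_id is not None and s.mother_id is not None:
            return _call(variant, family_id, phenotype, "de_novo", members)
    return None


_CHECKS = {
    "dominant": check_dominant,
    "recessive": check_recessive,
    "de_novo": check_de_novo,
}


def check_mode(
    variant: VariantRecord,
    pedigree: Pedigree,
    family_id: str,
    phenotype: str,
    mode: str,
) -> SegregationCall | None:
    try:
        fn = _CHECKS[mode]
    except KeyError:
        raise ValueError(f"unknown inheritance mode: {mode!r}")
    return fn(variant, pedigree, family_id, phenotype)


def scan_cohort(
    variants: Iterable[VariantRecord],
    pedigree: Pedigree,
    phenotypes: Sequence[str] | None = None,
    modes: Sequence[str] = MODES,
) -> list[SegregationCall]:
    """Scan every variant against every (family, phenotype, mode).

    A variant may yield calls in several families and phenotypes (shared
    diagnoses produce one call per phenotype).  Families without a full
    trio for a phenotype are skipped for that phenotype.
    """
    phenos = list(phenotypes) if phenotypes is not None else list(pedigree.phenotypes)
    for m in modes:
        if m not in _CHECKS:
            raise ValueError(f"unknown inheritance mode: {m!r}")
    eligible: dict[str, list[str]] = {
        p: [f for f in pedigree.families if family_has_full_trio(pedigree, f, p)]
        for p in phenos
    }
    calls: list[SegregationCall] = []
    for variant in variants:
        if not variant.is_autosomal:
            continue
        for phenotype in phenos:
            for family_id in eligible[phenotype]:
                for mode in modes:
                    call = _CHECKS[mode](variant, pedigree, family_id, phenotype)
                    if call is not None:
                        calls.append(call)
    return calls
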