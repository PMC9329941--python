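import itertools

import pytest

from mirfam.segregation import (
    check_de_novo,
    check_dominant,
    check_mode,
    check_recessive,
    family_has_full_trio,
    scan_cohort,
)

from conftest import make_pedigree, make_variant
from oracle_segregation import oracle

TRIO = [("dad", None, None), ("mom", None, None), ("kid", "dad", "mom")]
QUAD = TRIO + [("sib", "dad", "mom")]
THREEGEN = [
    ("gf", None, None),
    ("gm", None, None),
    ("dad", "gf", "gm"),
    ("mom", None, None),
    ("kid", "dad", "mom"),
]


def ped_from(members, statuses):
    return make_pedigree(
        [(sid, fa, mo, st) for (sid, fa, mo), st in zip(members, statuses)]
    )


class TestFullTrio:
    def test_affected_child_with_both_parents(self):
        ped = ped_from(TRIO, "uua")
        assert family_has_full_trio(ped, "F1", "P")

    def test_missing_parent_fails(self):
        ped = make_pedigree([("mom", None, None, "u"), ("kid", None, "mom", "a")])
        assert not family_has_full_trio(ped, "F1", "P")

    def test_unknown_phenotype_raises(self):
        ped = ped_from(TRIO, "uua")
        with pytest.raises(ValueError):
            family_has_full_trio(ped, "F1", "nope")


class TestCanonicalTrios:
    def test_dominant_affected_parent_transmits(self):
        ped = ped_from(TRIO, "aua")
        v = make_variant({"dad": 1, "mom": 0, "kid": 1})
        call = check_dominant(v, ped, "F1", "P")
        assert call is not None and set(call.carrier_samples) == {"dad", "kid"}

    def test_dominant_rejects_unaffected_parents(self):
        # both parents unaffected hom-ref: de novo territory, not dominant
        ped = ped_from(TRIO, "uua")
        v = make_variant({"dad": 0, "mom": 0, "kid": 1})
        assert check_dominant(v, ped, "F1", "P") is None
        assert check_de_novo(v, ped, "F1", "P") is not None

    def test_dominant_unaffected_carrier_sibling_vetoes(self):
        ped = ped_from(QUAD, "auau")
        v = make_variant({"dad": 1, "mom": 0, "kid": 1, "sib": 1})
        assert check_dominant(v, ped, "F1", "P") is None

    def test_recessive_carrier_parents(self):
        ped = ped_from(TRIO, "uua")
        v = make_variant({"dad": 1, "mom": 1, "kid": 2})
        assert check_recessive(v, ped, "F1", "P") is not None

    def test_recessive_hom_alt_unaffected_sibling_vetoes(self):
        ped = ped_from(QUAD, "uuau")
        v = make_variant({"dad": 1, "mom": 1, "kid": 2, "sib": 2})
        assert check_recessive(v, ped, "F1", "P") is None

    def test_de_novo_missing_parent_genotype_vetoes(self):
        ped = ped_from(TRIO, "uua")
        v = make_variant({"dad": None, "mom": 0, "kid": 1})
        assert check_de_novo(v, ped, "F1", "P") is None

    def test_unknown_status_carrier_is_ignored(self):
        ped = ped_from(QUAD, "aua?")
        v = make_variant({"dad": 1, "mom": 0, "kid": 1, "sib": 1})
        assert check_dominant(v, ped, "F1", "P") is not None


class TestExhaustiveTrioOracle:
    """All 27 trio genotype configurations under all affection patterns,
    for each mode, against the independent truth-table oracle."""

    @pytest.mark.parametrize("mode", ["dominant", "recessive", "de_novo"])
    def test_all_trio_configs(self, mode):
        sids = [m[0] for m in TRIO]
        for statuses in itertools.product("au?", repeat=3):
            ped = ped_from(TRIO, statuses)
            status = dict(zip(sids, statuses))
            for gts in itertools.product([0, 1, 2], repeat=3):
                v = make_variant(dict(zip(sids, gts)))
                got = check_mode(v, ped, "F1", "P", mode) is not None
                want = oracle(mode, TRIO, status, dict(zip(sids, gts)))
                assert got == want, (mode, statuses, gts)


class TestInvariants:
    def test_dominant_and_de_novo_mutually_exclusive(self):
        # exhaustive over the 3-generation family: an affected carrier
        # parent (dominant) and carrier-free parents (de novo) cannot coexist
        sids = [m[0] for m in THREEGEN]
        for statuses in itertools.product("au", repeat=5):
            ped = ped_from(THREEGEN, statuses)
            for gts in itertools.product([0, 1], repeat=5):
                v = make_variant(dict(zip(sids, gts)))
                dom = check_dominant(v, ped, "F1", "P") is not None
                dnv = check_de_novo(v, ped, "F1", "P") is not None
                assert not (dom and dnv)

    def test_adding_missingness_never_creates_a_call(self):
        sids = [m[0] for m in QUAD]
        for statuses in itertools.product("au", repeat=4):
            ped = ped_from(QUAD, statuses)
            for gts in itertools.product([0, 1, 2], repeat=4):
                base = dict(zip(sids, gts))
                for mode in ("dominant", "recessive", "de_novo"):
                    before = check_mode(make_variant(base), ped, "F1", "P", mode)
                    for drop in sids:
                        degraded = dict(base, **{drop: None})
                        after = check_mode(make_variant(degraded), ped, "F1", "P", mode)
                        # a call can only disappear, never appear
                        if after is not None:
                            assert before is not None

    def test_sex_chromosomes_never_called(self):
        ped = ped_from(TRIO, "aua")
        for chrom in ("chrX", "chrY", "chrMT"):
            v = make_variant({"dad": 1, "mom": 0, "kid": 1}, chrom=chrom)
            assert check_dominant(v, ped, "F1", "P") is None
        calls = scan_cohort(
            [make_variant({"dad": 1, "mom": 0, "kid": 1}, chrom="chrX")], ped
        )
        assert calls == []


class TestScanCohort:
    def test_empty_variants(self, bundle):
        assert scan_cohort([], bundle.pedigree) == []

    def test_planted_truth_recovery(self, bundle):
        """Every planted variant is called exactly for its designated
        (family, phenotype, mode), and the chrX decoy is never called."""
        truth = bundle.truth
        planted_keys = {
            (r.chrom, r.pos, r.ref, r.alt): r
            for r in truth.itertuples(index=False)
        }
        planted_variants = [v for v in bundle.variants if v.key in planted_keys]
        calls = scan_cohort(planted_variants, bundle.pedigree)
        by_key = {}
        for c in calls:
            by_key.setdefault(c.variant_key, []).append(c)
        for key, row in planted_keys.items():
            got = by_key.get(key, [])
            if row.source == "x_decoy":
                assert got == []
            else:
                assert len(got) == 1, (key, row.source, got)
                (call,) = got
                assert (call.family_id, call.phenotype, call.mode) == (
                    row.family_id,
                    row.phenotype,
                    row.mode,
                )

    def test_shared_diagnosis_yields_one_call_per_phenotype(self):
        members = [("dad", None, None), ("mom", None, None), ("kid", "dad", "mom")]
        from mirfam.io_formats import Affection, Pedigree, Sample

        aff = {
            "dad": {"LI": Affection.AFFECTED, "RI": Affection.AFFECTED},
            "mom": {"LI": Affection.UNAFFECTED, "RI": Affection.UNAFFECTED},
            "kid": {"LI": Affection.AFFECTED, "RI": Affection.AFFECTED},
        }
        ped = Pedigree(
            [
                Sample(sid, "F1", fa, mo, "unknown", aff[sid])
                for sid, fa, mo in members
            ],
            ["LI", "RI"],
        )
        v = make_variant({"dad": 1, "mom": 0, "kid": 1})
        calls = scan_cohort([v], ped)
        assert {(c.phenotype, c.mode) for c in calls} == {
            ("LI", "dominant"),
            ("RI", "dominant"),
        }
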