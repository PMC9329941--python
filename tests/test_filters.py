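import itertools

import pytest

from mirfam.examples import MIRNA_CANDIDATE_ROWS, example_af_records
from mirfam.filters import (
    AfThresholds,
    CohortAf,
    apply_mirna_cascade,
    is_brain_expressed,
    passes_af_filter,
)
from mirfam.io_formats import AfRecord, ExpressionRecord, variant_key

from conftest import make_pedigree, make_variant

KEY = ("chr1", 100, "A", "G")


def af(values, dataset_prefix="d", qc_pass=True):
    return [
        AfRecord(key=KEY, dataset_id=f"{dataset_prefix}{i}", af=v, qc_pass=qc_pass)
        for i, v in enumerate(values)
    ]


def two_family_cohort(outside_carrier, n_pad=0):
    """Two trios plus ``n_pad`` unrelated hom-ref samples; the variant is
    carried inside family FA and optionally by one sample in FB."""
    from mirfam.io_formats import Affection, Pedigree, Sample

    samples = []
    for fam in ("FA", "FB"):
        for role, fa, mo in (("d", None, None), ("m", None, None), ("k", "d", "m")):
            sid = f"{fam}{role}"
            samples.append(
                Sample(sid, fam, f"{fam}{fa}" if fa else None,
                       f"{fam}{mo}" if mo else None, "unknown",
                       {"P": Affection.UNAFFECTED})
            )
    for i in range(n_pad):
        samples.append(
            Sample(f"P{i}", f"FP{i}", None, None, "unknown", {"P": Affection.UNAFFECTED})
        )
    ped = Pedigree(samples, ["P"])
    gts = {s.sample_id: 0 for s in samples}
    gts["FAk"] = 1
    if outside_carrier:
        gts["FBk"] = 1
    v = make_variant(gts)
    return ped, v


class TestThresholds:
    def test_domain_validation(self):
        with pytest.raises(ValueError):
            AfThresholds(0.01, 0.02)  # de novo cutoff above dominant
        with pytest.raises(ValueError):
            AfThresholds(1.0, 0.001)

    def test_mode_lookup(self):
        t = AfThresholds()
        assert t.for_mode("dominant") == t.for_mode("recessive") == 0.01
        assert t.for_mode("de_novo") == 0.001
        with pytest.raises(ValueError):
            t.for_mode("x_linked")


class TestPassesAfFilter:
    def test_published_dominant_candidates_all_pass(self):
        """The five printed reference-AF triples all clear the dominant
        1% cutoff in every dataset where they are reported."""
        for key, records in example_af_records().items():
            passed, reason = passes_af_filter(key, "dominant", records, None)
            assert passed, (key, reason)

    def test_all_datasets_rule(self):
        passed, _ = passes_af_filter(KEY, "dominant", af([0.5, 1e-6]), None)
        assert not passed  # one dataset at 50% sinks it

    def test_strict_inequality_at_cutoff(self):
        passed, _ = passes_af_filter(KEY, "dominant", af([0.01]), None)
        assert not passed
        passed, _ = passes_af_filter(KEY, "de_novo", af([0.001]), None)
        assert not passed

    def test_qc_failed_records_fall_back_to_cohort(self):
        # 60 extra samples keep the cohort AF of one carrier below 1%
        ped, v = two_family_cohort(outside_carrier=False, n_pad=60)
        cohort = CohortAf([v], ped)
        # reference rows exist but failed QC -> treated as absent
        passed, reason = passes_af_filter(
            v.key, "dominant", af([0.9], qc_pass=False), cohort, family_id="FA"
        )
        assert passed and "cohort" in reason

    def test_de_novo_fallback_requires_private_allele(self):
        ped, v = two_family_cohort(outside_carrier=True)
        cohort = CohortAf([v], ped)
        passed, _ = passes_af_filter(v.key, "de_novo", [], cohort, family_id="FA")
        assert not passed
        ped2, v2 = two_family_cohort(outside_carrier=False)
        cohort2 = CohortAf([v2], ped2)
        passed, _ = passes_af_filter(v2.key, "de_novo", [], cohort2, family_id="FA")
        assert passed

    def test_dominant_fallback_uses_cohort_frequency(self):
        ped, v = two_family_cohort(outside_carrier=False)
        cohort = CohortAf([v], ped)
        # 1 alt allele / 12 ~ 8.3% >= 1% -> fail
        passed, _ = passes_af_filter(v.key, "dominant", [], cohort, family_id="FA")
        assert not passed


class TestBrainExpression:
    def test_any_dataset_rule(self):
        recs = {
            "g": [
                ExpressionRecord("g", "d1", 0.1),
                ExpressionRecord("g", "d2", 6.2),
                ExpressionRecord("g", "d3", 1.0),
            ]
        }
        assert is_brain_expressed("g", recs)

    def test_strictly_greater_boundary(self):
        recs = {"g": [ExpressionRecord("g", "d1", 5.0), ExpressionRecord("g", "d2", 5.0)]}
        assert not is_brain_expressed("g", recs)

    def test_unknown_feature_not_expressed(self):
        assert not is_brain_expressed("nope", {})


class TestMirnaCascade:
    def test_funnel_monotone_and_planted_recovery(self, bundle, pipeline_result):
        funnel = pipeline_result.report["mirna_funnel"]
        order = ["mirna_overlap", "segregating", "seed_mature", "brain_expressed", "af_pass"]
        counts = [funnel[k] for k in order]
        assert counts == sorted(counts, reverse=True)
        truth = bundle.truth
        mirna = truth[truth.funnel == "mirna"]
        assert funnel["mirna_overlap"] == int(mirna.expect_overlap.sum())
        assert funnel["segregating"] == int(mirna.expect_segregating.sum())
        assert funnel["seed_mature"] == int(mirna.expect_region.sum())
        assert funnel["brain_expressed"] == int(mirna.expect_expressed.sum())
        assert funnel["af_pass"] == int(mirna.expect_af.sum())

    def test_loop_variant_removed_at_region_stage(self, bundle, pipeline_result):
        loop_rows = bundle.truth[bundle.truth.source == "mirna_loop"]
        loop_keys = {
            (r.chrom, int(r.pos), r.ref, r.alt) for r in loop_rows.itertuples()
        }
        surviving = {c.variant_key for c in pipeline_result.mirna_candidates}
        assert loop_keys and not (loop_keys & surviving)

    def test_threshold_monotonicity(self, bundle, pipeline_result):
        """Raising AF cutoffs never removes a survivor."""
        from mirfam.filters import apply_mirna_cascade
        from mirfam.io_formats import af_records_from_table, read_interval_table, expression_records_from_table
        from mirfam.filters import CohortAf

        cfg = pipeline_result.config
        expression = expression_records_from_table(
            read_interval_table(cfg.expression, "expression")
        )
        af_map = af_records_from_table(read_interval_table(cfg.af, "af"))
        cohort = CohortAf(bundle.variants, bundle.pedigree)
        tight, _ = apply_mirna_cascade(
            pipeline_result.region_calls, pipeline_result.segregation_calls,
            expression, af_map, AfThresholds(0.01, 0.001), cohort,
        )
        loose, _ = apply_mirna_cascade(
            pipeline_result.region_calls, pipeline_result.segregation_calls,
            expression, af_map, AfThresholds(0.5, 0.1), cohort,
        )
        assert {c.variant_key for c in tight} <= {c.variant_key for c in loose}
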