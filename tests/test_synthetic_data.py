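import filecmp

import pytest

from mirfam.io_formats import read_interval_table
from mirfam.synthetic_data import (
    MIRNA_SOURCES,
    PlantSpec,
    SimConfig,
    default_plants,
    simulate_bundle,
    write_bundle,
)


class TestConfigValidation:
    def test_dominant_asd_plant_is_infeasible(self):
        cfg = SimConfig(plants=(PlantSpec("dominant", "mirna_seed", "ASD"),))
        with pytest.raises(ValueError, match="dominant.*ASD"):
            cfg.validate()

    def test_too_many_plants(self):
        plants = tuple(PlantSpec("de_novo", "mirna_seed", "ASD") for _ in range(5))
        with pytest.raises(ValueError, match="plant"):
            SimConfig(n_trio=2, n_quad=1, n_threegen=1, plants=plants).validate()

    def test_bad_strata_proportions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(af_strata_proportions={"rare": 0.5, "low": 0.2, "common": 0.2}).validate()

    def test_default_plants_cover_all_strata(self):
        plants = default_plants()
        assert len(plants) >= 20
        assert {p.mode for p in plants} == {"dominant", "recessive", "de_novo"}
        assert {p.source for p in plants} >= set(MIRNA_SOURCES)
        assert {p.af_stratum for p in plants} == {"rare", "low", "common", "absent", "fail_qc"}
        assert {p.expressed for p in plants} == {True, False}


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimConfig(rng_seed=7, n_background_variants=40)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_bundle(simulate_bundle(cfg), d1)
        p2 = write_bundle(simulate_bundle(cfg), d2)
        for name in p1:
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name

    def test_different_seed_differs(self, tmp_path):
        a = simulate_bundle(SimConfig(rng_seed=1, n_background_variants=40))
        b = simulate_bundle(SimConfig(rng_seed=2, n_background_variants=40))
        assert any(
            va.genotypes != vb.genotypes for va, vb in zip(a.variants, b.variants)
        )


class TestCohortStructure:
    def test_default_shape(self, bundle):
        assert len(bundle.pedigree) == 272
        assert len(bundle.pedigree.families) == 73

    def test_mendelian_consistency_outside_de_novo_plants(self, bundle):
        """Excluding planted de novo sites, every child genotype is
        producible from its parents' genotypes."""
        de_novo_keys = {
            (r.chrom, int(r.pos), r.ref, r.alt)
            for r in bundle.truth.itertuples()
            if r.mode == "de_novo" or r.source == "x_decoy"
        }
        ped = bundle.pedigree
        compatible = {  # child count -> allowed (father, mother) count pairs
            0: lambda f, m: f < 2 and m < 2,
            1: lambda f, m: not (f == 0 and m == 0) and not (f == 2 and m == 2),
            2: lambda f, m: f > 0 and m > 0,
        }
        for v in bundle.variants:
            if v.key in de_novo_keys:
                continue
            for s in ped.samples:
                if s.father_id is None or s.mother_id is None:
                    continue
                c = v.genotypes[s.sample_id]
                f = v.genotypes[s.father_id]
                m = v.genotypes[s.mother_id]
                if None in (c, f, m):
                    continue
                assert compatible[c](f, m), (v.key, s.sample_id, c, f, m)

    def test_planted_positions_match_their_stratum(self, bundle):
        regions = bundle.mirna_regions
        sites = bundle.target_sites
        for r in bundle.truth.itertuples():
            pos0 = int(r.pos) - 1
            if r.source in ("mirna_seed", "x_decoy"):
                hit = regions[
                    (regions.region == "seed")
                    & (regions.chrom == r.chrom)
                    & (regions.start <= pos0)
                    & (pos0 < regions.end)
                ]
                assert len(hit) == 1, r
            elif r.source == "mirna_loop":
                hit = regions[
                    (regions.region == "loop")
                    & (regions.start <= pos0)
                    & (pos0 < regions.end)
                ]
                assert len(hit) == 1
            elif r.source.startswith("utr_site"):
                hit = sites[(sites.utr_start <= pos0) & (pos0 < sites.utr_end)]
                assert len(hit) == 1
                if r.source == "utr_site_fail_cs":
                    assert -0.4 < float(hit.context_score.iloc[0]) < 0
                elif r.source == "utr_site_fail_cons":
                    assert hit.conservation_class.iloc[0] == "poorly_conserved"
                else:
                    assert hit.conservation_class.iloc[0] in (
                        "broadly_conserved", "conserved",
                    )
                    assert float(hit.context_score.iloc[0]) < -0.4

    def test_af_strata_realized(self, bundle):
        af = bundle.af_table
        for r in bundle.truth.itertuples():
            rows = af[(af.chrom == r.chrom) & (af.pos == r.pos)]
            present = rows[rows.af.notna()] if len(rows) else rows
            if r.af_stratum == "absent":
                assert rows.empty
            elif r.af_stratum == "common":
                assert (present.af > 1e-2).any()
            elif r.af_stratum == "low":
                assert present.af.dropna().between(1e-3, 1e-2).all()
            elif r.af_stratum == "rare":
                assert present.af.dropna().lt(1e-3).all()
            elif r.af_stratum == "fail_qc":
                assert not rows["pass"].any()

    def test_written_tables_parse_cleanly(self, bundle_paths):
        for kind, name in [
            ("mirna_regions", "mirna_regions"),
            ("utr_regions", "utr_regions"),
            ("target_sites", "target_sites"),
            ("af", "af"),
            ("expression", "expression"),
            ("ppi", "ppi"),
            ("go", "go"),
        ]:
            df = read_interval_table(bundle_paths[name], kind)
            assert df.attrs["n_rejected"] == 0
            assert len(df) > 0
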