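import pytest

from mirfam.io_formats import Affection, Pedigree, Sample, VariantRecord
from mirfam.pipeline import PipelineConfig, run_pipeline
from mirfam.synthetic_data import SimConfig, simulate_bundle, write_bundle


def make_pedigree(members, phenotype="P"):
    """Build a one-family pedigree from (sid, father, mother, status) rows;
    status is 'a'ffected / 'u'naffected / '?'nknown for the one phenotype."""
    code = {"a": Affection.AFFECTED, "u": Affection.UNAFFECTED, "?": Affection.UNKNOWN}
    samples = [
        Sample(
            sample_id=sid,
            family_id="F1",
            father_id=fa,
            mother_id=mo,
            sex="unknown",
            affection={phenotype: code[st]},
        )
        for sid, fa, mo, st in members
    ]
    return Pedigree(samples, [phenotype])


def make_variant(genotypes, chrom="chr1", pos=100, ref="A", alt="G"):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=dict(genotypes))


@pytest.fixture(scope="session")
def bundle():
    return simulate_bundle(SimConfig(rng_seed=1))


@pytest.fixture(scope="session")
def bundle_paths(bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    return write_bundle(bundle, outdir)


@pytest.fixture(scope="session")
def pipeline_config(bundle_paths):
    return PipelineConfig(
        vcf=str(bundle_paths["vcf"]),
        ped=str(bundle_paths["ped"]),
        mirna_gff=str(bundle_paths["mirna_gff"]),
        mirna_regions=str(bundle_paths["mirna_regions"]),
        utr_regions=str(bundle_paths["utr_regions"]),
        target_sites=str(bundle_paths["target_sites"]),
        af=str(bundle_paths["af"]),
        expression=str(bundle_paths["expression"]),
        ppi=str(bundle_paths["ppi"]),
        go=str(bundle_paths["go"]),
        ndd_genes=str(bundle_paths["ndd_genes"]),
    )


@pytest.fixture(scope="session")
def pipeline_result(pipeline_config):
    return run_pipeline(pipeline_config)
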