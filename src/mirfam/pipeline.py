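"""End-to-end orchestration: read inputs, run both funnels, integrate.

The pipeline mirrors the two-funnel design of family-based miRNA variant
prioritization:

* miRNA funnel — variants inside miRNA hairpins, filtered by inheritance
  pattern, functional region (seed/mature), miRNA brain expression, and
  mode-specific population AF;
* 3'UTR funnel — variants inside 3'UTRs, filtered by inheritance
  pattern, overlap with conserved high-efficacy predicted binding sites,
  target-gene brain expression, and the same AF rules.

Every stage logs its unique-variant survivor count into a run report (a
machine-readable funnel); downstream integration produces candidate
tables, gene summaries, family Venn partitions, dual-evidence and
recurrent genes, GO over-representation, and consensus PPI subnetworks.
All computation is deterministic given the inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from intervaltree import IntervalTree

from . import io_formats as iof
from .filters import AfThresholds, CohortAf, apply_mirna_cascade, is_brain_expressed, passes_af_filter
from .integration import (
    CandidateCall,
    dual_evidence_genes,
    family_venn,
    go_overrepresentation,
    recurrent_genes,
    summarize_by_phenotype,
)
from .mirna_annotation import build_region_index, classify_variant, read_mirna_annotations
from .network import assert_simple_undirected, build_consensus_network, candidate_subgraph, ndd_augmented_subgraph
from .segregation import MODES, scan_cohort
from .target_sites import UtrVariantHit, mirna_target_genes, overlap_utr_variants, sites_from_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_outputs"]


@dataclass
class PipelineConfig:
    """Input paths and thresholds for one pipeline run."""

    vcf: str
    ped: str
    mirna_gff: str
    mirna_regions: str
    utr_regions: str
    target_sites: str
    af: str
    expression: str
    ppi: str | None = None
    go: str | None = None
    ndd_genes: str | None = None
    output_dir: str | None = None
    phenotypes: list[str] = field(
        default_factory=lambda: ["ASD", "LI", "RI", "SRS", "ADHD"]
    )
    modes: list[str] = field(default_factory=lambda: list(MODES))
    dominant_recessive_af_max: float = 0.01
    de_novo_af_max: float = 0.001
    tpm_min: float = 5.0
    cs_max: float = -0.4
    min_db_support: int = 2
    max_term_size: int = 600
    q_max: float = 0.05
    max_degree_shown: int = 13

    @property
    def thresholds(self) -> AfThresholds:
        return AfThresholds(self.dominant_recessive_af_max, self.de_novo_af_max)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    report: dict
    region_calls: list
    segregation_calls: list
    mirna_candidates: list
    utr_hits: list[UtrVariantHit]
    utr_candidates: list[CandidateCall]
    mirna_candidate_calls: list[CandidateCall]
    mirna_target_sets: dict[str, set[str]]
    dual_evidence: pd.DataFrame
    recurrent: list[str]
    gene_summary: pd.DataFrame
    venn: dict[str, dict[frozenset, int]]
    enrichment: dict[str, list]
    consensus_graph: object
    candidate_graph: object


def _max_af(records) -> float | None:
    vals = [r.af for r in records if r.qc_pass and r.af is not None]
    return max(vals) if vals else None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    thresholds = config.thresholds
    pedigree = iof.read_ped(config.ped, config.phenotypes)
    all_variants = list(iof.read_vcf(config.vcf))
    variants = [v for v in all_variants if v.qual_pass]

    annotations = read_mirna_annotations(config.mirna_gff, config.mirna_regions)
    index = build_region_index(annotations)

    region_calls = []
    mirna_variant_keys = set()
    for v in variants:
        calls = classify_variant(v, index)
        region_calls.extend(calls)
        if calls:
            mirna_variant_keys.add(v.key)

    utr_table = iof.read_interval_table(config.utr_regions, "utr_regions")
    utr_trees: dict[str, IntervalTree] = {}
    for row in utr_table.itertuples(index=False):
        utr_trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.gene)
    utr_variants = [
        v
        for v in variants
        if v.chrom in utr_trees and utr_trees[v.chrom].overlap(v.start, v.end)
    ]
    utr_keys = {v.key for v in utr_variants}

    # segregation is only consulted for variants inside either funnel
    funnel_variants = [v for v in variants if v.key in mirna_variant_keys or v.key in utr_keys]
    segregation_calls = scan_cohort(funnel_variants, pedigree, config.phenotypes, config.modes)
    seg_by_variant: dict[tuple, list] = {}
    for sc in segregation_calls:
        seg_by_variant.setdefault(sc.variant_key, []).append(sc)

    cohort_af = CohortAf(variants, pedigree)
    af_by_variant = iof.af_records_from_table(iof.read_interval_table(config.af, "af"))
    expression = iof.expression_records_from_table(
        iof.read_interval_table(config.expression, "expression")
    )

    # --- miRNA funnel -------------------------------------------------------
    mirna_candidates, mirna_funnel = apply_mirna_cascade(
        region_calls,
        segregation_calls,
        expression,
        af_by_variant,
        thresholds=thresholds,
        cohort_af=cohort_af,
        tpm_min=config.tpm_min,
    )
    mirna_candidate_calls = [
        CandidateCall(
            variant_key=c.variant_key,
            source="mirna",
            gene=c.mirna_name,
            family_id=c.family_id,
            phenotype=c.phenotype,
            mode=c.mode,
            af_summary=_max_af(af_by_variant.get(c.variant_key, [])),
        )
        for c in mirna_candidates
    ]

    # --- 3'UTR funnel -------------------------------------------------------
    sites = sites_from_table(iof.read_interval_table(config.target_sites, "target_sites"))
    utr_funnel: dict[str, int] = {"in_utr": len(utr_keys)}
    segregating_utr = [v for v in utr_variants if v.key in seg_by_variant]
    utr_funnel["segregating"] = len({v.key for v in segregating_utr})
    utr_hits = overlap_utr_variants(segregating_utr, sites, cs_max=config.cs_max)
    hits_by_variant: dict[tuple, list[UtrVariantHit]] = {}
    for h in utr_hits:
        hits_by_variant.setdefault(h.variant_key, []).append(h)
    utr_funnel["conserved_site"] = len(hits_by_variant)

    expressed_hit_keys = set()
    utr_candidates: list[CandidateCall] = []
    af_pass_keys = set()
    for vkey, hits in hits_by_variant.items():
        genes = {h.gene for h in hits}
        expressed_genes = {
            g for g in genes if is_brain_expressed(g, expression, config.tpm_min)
        }
        if not expressed_genes:
            continue
        expressed_hit_keys.add(vkey)
        for sc in seg_by_variant[vkey]:
            passed, _ = passes_af_filter(
                vkey, sc.mode, af_by_variant.get(vkey, []), cohort_af,
                thresholds, family_id=sc.family_id,
            )
            if not passed:
                continue
            af_pass_keys.add(vkey)
            for gene in sorted(expressed_genes):
                utr_candidates.append(
                    CandidateCall(
                        variant_key=vkey,
                        source="utr",
                        gene=gene,
                        family_id=sc.family_id,
                        phenotype=sc.phenotype,
                        mode=sc.mode,
                        af_summary=_max_af(af_by_variant.get(vkey, [])),
                    )
                )
    utr_funnel["brain_expressed"] = len(expressed_hit_keys)
    utr_funnel["af_pass"] = len(af_pass_keys)

    # --- integration --------------------------------------------------------
    candidate_mirna_matures = sorted(
        {c.mature_name for c in mirna_candidates if c.mature_name is not None}
    )
    mirna_target_sets = {
        m: mirna_target_genes(m, sites, expression, config.cs_max, config.tpm_min)
        for m in candidate_mirna_matures
    }
    dual = dual_evidence_genes(mirna_target_sets, utr_candidates)
    recurrent = recurrent_genes(utr_candidates)
    gene_summary = summarize_by_phenotype(
        utr_candidates, phenotypes=config.phenotypes, modes=list(config.modes)
    )
    venn = {mode: family_venn(utr_candidates, mode) for mode in config.modes}

    enrichment: dict[str, list] = {}
    if config.go is not None:
        go_table = iof.read_interval_table(config.go, "go")
        background = set(go_table["gene"])
        target_union = set().union(*mirna_target_sets.values()) if mirna_target_sets else set()
        for phenotype in config.phenotypes:
            query = {c.gene for c in utr_candidates if c.phenotype == phenotype}
            query |= {
                g
                for c in mirna_candidates
                if c.phenotype == phenotype and c.mature_name in mirna_target_sets
                for g in mirna_target_sets[c.mature_name]
            }
            query &= background  # unannotated genes cannot be tested
            if not query:
                continue
            enrichment[phenotype] = go_overrepresentation(
                query, go_table, background, config.max_term_size, config.q_max
            )
        _ = target_union

    consensus_graph = None
    candidate_graph = None
    network_report: dict = {}
    if config.ppi is not None:
        ppi_table = iof.read_interval_table(config.ppi, "ppi")
        consensus_graph = build_consensus_network(ppi_table, config.min_db_support)
        assert_simple_undirected(consensus_graph)
        candidate_gene_pool = set(
            g for s in mirna_target_sets.values() for g in s
        ) | {c.gene for c in utr_candidates}
        candidate_graph = candidate_subgraph(consensus_graph, candidate_gene_pool)
        network_report = {
            "consensus_edges": consensus_graph.number_of_edges(),
            "consensus_nodes": consensus_graph.number_of_nodes(),
            "candidate_nodes": candidate_graph.number_of_nodes(),
            "candidate_edges": candidate_graph.number_of_edges(),
        }
        if config.ndd_genes is not None:
            ndd = set(Path(config.ndd_genes).read_text().split())
            augmented, hidden = ndd_augmented_subgraph(
                consensus_graph, candidate_gene_pool, ndd, config.max_degree_shown
            )
            network_report["ndd_augmented_nodes"] = augmented.number_of_nodes()
            network_report["ndd_augmented_edges"] = augmented.number_of_edges()
            network_report["ndd_hidden_hubs"] = len(hidden)

    report = {
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if not isinstance(v, (list,)) or k in ("phenotypes", "modes")
        },
        "inputs": {
            "n_samples": len(pedigree),
            "n_families": len(pedigree.families),
            "n_variants": len(all_variants),
            "n_variants_qual_pass": len(variants),
            "n_mirna_precursors": index.n_precursors,
        },
        "mirna_funnel": mirna_funnel,
        "utr_funnel": utr_funnel,
        "candidates": {
            "mirna_variants": len({c.variant_key for c in mirna_candidates}),
            "mirna_names": sorted({c.mirna_name for c in mirna_candidates}),
            "utr_variants": len({c.variant_key for c in utr_candidates}),
            "utr_genes": len({c.gene for c in utr_candidates}),
            "mirna_target_genes": len(set().union(*mirna_target_sets.values()))
            if mirna_target_sets
            else 0,
            "dual_evidence_genes": len(dual),
            "recurrent_genes": recurrent,
        },
        "gene_counts": {
            str(k): {str(c): int(x) for c, x in row.items()}
            for k, row in gene_summary.to_dict(orient="index").items()
        },
        "family_venn": {
            mode: {"+".join(sorted(cell)): n for cell, n in cells.items()}
            for mode, cells in venn.items()
        },
        "enrichment": {
            p: {
                "n_tested": len(res),
                "n_enriched": sum(r.enriched for r in res),
            }
            for p, res in enrichment.items()
        },
        "network": network_report,
    }

    return PipelineResult(
        config=config,
        report=report,
        region_calls=region_calls,
        segregation_calls=segregation_calls,
        mirna_candidates=mirna_candidates,
        utr_hits=utr_hits,
        utr_candidates=utr_candidates,
        mirna_candidate_calls=mirna_candidate_calls,
        mirna_target_sets=mirna_target_sets,
        dual_evidence=dual,
        recurrent=recurrent,
        gene_summary=gene_summary,
        venn=venn,
        enrichment=enrichment,
        consensus_graph=consensus_graph,
        candidate_graph=candidate_graph,
    )


def _key_str(key: tuple) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


def write_outputs(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write every primary output table plus the JSON run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)

    _write(
        "region_calls",
        pd.DataFrame(
            [
                {"variant": _key_str(rc.variant_key), "mirna_name": rc.mirna_name,
                 "region": rc.region, "mature_name": rc.mature_name or ""}
                for rc in result.region_calls
            ]
        ),
    )
    _write(
        "segregation",
        pd.DataFrame(
            [
                {"variant": _key_str(sc.variant_key), "family": sc.family_id,
                 "phenotype": sc.phenotype, "mode": sc.mode,
                 "carriers": ";".join(sc.carrier_samples)}
                for sc in result.segregation_calls
            ]
        ),
    )
    _write(
        "mirna_candidates",
        pd.DataFrame(
            [
                {"variant": _key_str(c.variant_key), "mirna": c.mirna_name,
                 "mature": c.mature_name or "", "region": c.region,
                 "family": c.family_id, "phenotype": c.phenotype, "mode": c.mode,
                 "af_reason": c.af_reason}
                for c in result.mirna_candidates
            ]
        ),
    )
    _write(
        "utr_candidates",
        pd.DataFrame(
            [
                {"variant": _key_str(c.variant_key), "gene": c.gene,
                 "family": c.family_id, "phenotype": c.phenotype, "mode": c.mode,
                 "af_max": "" if c.af_summary is None else c.af_summary}
                for c in result.utr_candidates
            ]
        ),
    )
    _write("dual_evidence", result.dual_evidence)
    enrich_rows = [
        {"phenotype": p, "term_id": r.term_id, "term_name": r.term_name,
         "overlap": r.overlap_count, "term_size": r.term_size,
         "p_value": r.p_value, "q_value": r.q_value, "enriched": r.enriched}
        for p, res in result.enrichment.items()
        for r in res
    ]
    _write("enrichment", pd.DataFrame(enrich_rows))
    if result.candidate_graph is not None:
        _write(
            "network_edges",
            pd.DataFrame(
                [
                    {"gene_a": a, "gene_b": b,
                     "support": result.candidate_graph.edges[a, b]["support"],
                     "source_dbs": ";".join(result.candidate_graph.edges[a, b]["source_dbs"])}
                    for a, b in sorted(result.candidate_graph.edges)
                ]
            ),
        )
    paths["report"] = outdir / "report.json"
    with open(paths["report"], "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
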