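import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirfam.examples import example_mirna_target_sets, example_utr_calls
from mirfam.integration import (
    CandidateCall,
    dual_evidence_genes,
    family_venn,
    go_overrepresentation,
    recurrent_genes,
    summarize_by_phenotype,
)


def call(gene, family, phenotype, mode="dominant", source="utr"):
    return CandidateCall(
        variant_key=("chr1", 1, "A", "G"), source=source, gene=gene,
        family_id=family, phenotype=phenotype, mode=mode,
    )


def hypergeom_tail_oracle(k, N, K, n):
    """Exact upper-tail P(X >= k) by direct summation of the
    hypergeometric mass function using integer combinatorics."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


class TestSummarize:
    def test_empty_calls_all_zero(self):
        df = summarize_by_phenotype([], phenotypes=["ASD", "LI"])
        assert (df.values == 0).all()

    def test_union_marginals_match_set_oracle(self):
        rng = np.random.default_rng(5)
        phenos = ["ASD", "LI", "RI"]
        modes = ["dominant", "recessive", "de_novo"]
        calls = [
            call(f"G{int(rng.integers(12))}", "F1", phenos[int(rng.integers(3))],
                 mode=modes[int(rng.integers(3))])
            for _ in range(60)
        ]
        df = summarize_by_phenotype(calls, phenotypes=phenos, modes=modes)
        sets = {
            (m, p): {c.gene for c in calls if c.mode == m and c.phenotype == p}
            for m in modes for p in phenos
        }
        for m in modes:
            for p in phenos:
                assert df.loc[m, p] == len(sets[(m, p)])
            assert df.loc[m, "total_unique"] == len(set().union(*(sets[(m, p)] for p in phenos)))
        for p in phenos:
            assert df.loc["total_unique", p] == len(set().union(*(sets[(m, p)] for m in modes)))
        grand = set().union(*sets.values())
        assert df.loc["total_unique", "total_unique"] == len(grand)
        # marginals are unions: never exceed the sum of their parts
        for m in modes:
            assert df.loc[m, "total_unique"] <= sum(df.loc[m, p] for p in phenos)


class TestVenn:
    def test_single_family_single_phenotype(self):
        assert family_venn([call("G", "F1", "RI")], "dominant") == {frozenset({"RI"}): 1}

    def test_multi_phenotype_family_counted_in_intersection_only(self):
        calls = [call("G1", "F1", "RI"), call("G2", "F1", "SRS")]
        venn = family_venn(calls, "dominant")
        assert venn == {frozenset({"RI", "SRS"}): 1}

    def test_partition_conserves_family_count(self):
        rng = np.random.default_rng(9)
        phenos = ["ASD", "LI", "RI", "SRS"]
        calls = [
            call(f"G{i}", f"F{int(rng.integers(10))}", phenos[int(rng.integers(4))])
            for i in range(80)
        ]
        venn = family_venn(calls, "dominant")
        assert sum(venn.values()) == len({c.family_id for c in calls})
        # brute-force partition oracle
        by_fam = {}
        for c in calls:
            by_fam.setdefault(c.family_id, set()).add(c.phenotype)
        for cell, n in venn.items():
            assert n == sum(1 for s in by_fam.values() if frozenset(s) == cell)


class TestDualEvidenceAndRecurrence:
    def test_disjoint_sets_empty(self):
        df = dual_evidence_genes({"miR-1": {"A"}}, [call("B", "F1", "RI")])
        assert df.empty

    def test_worked_example_counts(self):
        """The published top-gene table yields four dual-evidence genes
        and two multi-family multi-phenotype genes."""
        dual = dual_evidence_genes(example_mirna_target_sets(), example_utr_calls())
        assert sorted(dual["gene"]) == ["ONECUT2", "OSBP", "SCP2", "TUB"]
        rec = recurrent_genes(example_utr_calls())
        assert rec == ["RBM24", "UGCG"]

    def test_recurrence_patterns(self):
        # two families but one phenotype: excluded
        osbp_like = [call("G", "F1", "RI"), call("G", "F2", "RI")]
        assert recurrent_genes(osbp_like) == []
        # three families, two phenotypes: included
        ugcg_like = osbp_like + [call("G", "F3", "SRS")]
        assert recurrent_genes(ugcg_like) == ["G"]
        # degenerate thresholds admit every called gene
        assert recurrent_genes(osbp_like, min_families=1, min_phenotypes=1) == ["G"]

    def test_synthetic_intersection_oracle(self):
        rng = np.random.default_rng(2)
        targets = {f"miR-{i}": {f"G{int(g)}" for g in rng.integers(0, 30, 8)} for i in range(4)}
        calls = [call(f"G{int(g)}", "F1", "RI") for g in rng.integers(0, 30, 12)]
        df = dual_evidence_genes(targets, calls)
        want = set().union(*targets.values()) & {c.gene for c in calls}
        assert set(df["gene"]) == want


class TestEnrichment:
    def annotation(self, term_sizes, n_genes=1000):
        rows = []
        rng = np.random.default_rng(42)
        genes = [f"G{i}" for i in range(n_genes)]
        for t, size in enumerate(term_sizes):
            for g in rng.choice(n_genes, size=size, replace=False):
                rows.append({"term_id": f"T{t}", "term_name": f"term {t}", "gene": genes[int(g)]})
        # every gene annotated somewhere so the default background is complete
        for g in genes:
            rows.append({"term_id": "ROOT", "term_name": "root", "gene": g})
        return pd.DataFrame(rows), genes

    def test_query_equals_background_gives_p_one(self):
        ann, genes = self.annotation([5, 20])
        res = go_overrepresentation(set(genes), ann, max_term_size=2000)
        assert all(abs(r.p_value - 1.0) < 1e-12 for r in res)

    def test_exact_tail_against_combinatorial_oracle(self):
        ann, genes = self.annotation([5])
        query = set(genes[:50])
        term5 = {r.gene for r in ann.itertuples() if r.term_id == "T0"}
        k = len(term5 & query)
        res = {r.term_id: r for r in go_overrepresentation(query, ann, max_term_size=2000)}
        want = hypergeom_tail_oracle(k, 1000, 5, 50)
        assert abs(res["T0"].p_value - want) < 1e-12

    def test_size_cap_excludes_large_terms(self):
        ann, genes = self.annotation([5, 700])
        res = go_overrepresentation(set(genes[:10]), ann, max_term_size=600)
        assert {r.term_id for r in res} == {"T0"}  # T1 and ROOT too large

    def test_bh_qvalues_monotone_in_p_rank(self):
        ann, genes = self.annotation([5, 10, 20, 40, 80])
        res = go_overrepresentation(set(genes[:60]), ann, max_term_size=2000)
        ordered = sorted(res, key=lambda r: r.p_value)
        qs = [r.q_value for r in ordered]
        assert qs == sorted(qs)

    def test_input_order_invariance(self):
        ann, genes = self.annotation([5, 10, 20])
        shuffled = ann.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = go_overrepresentation(set(genes[:30]), ann, max_term_size=2000)
        b = go_overrepresentation(set(genes[:30]), shuffled, max_term_size=2000)
        assert [(r.term_id, r.p_value, r.q_value) for r in a] == [
            (r.term_id, r.p_value, r.q_value) for r in b
        ]

    def test_errors(self):
        ann, genes = self.annotation([5])
        with pytest.raises(ValueError, match="background"):
            go_overrepresentation({"G0"}, ann.iloc[0:0], background=set())
        with pytest.raises(ValueError, match="absent"):
            go_overrepresentation({"NOT_A_GENE"}, ann)
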