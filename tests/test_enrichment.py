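"""Gene-set variation scoring, name filtering and differential calls."""

import math

import numpy as np
import pandas as pd
import pytest

from rteaging.cohort import SampleGrouping
from rteaging.enrichment import (
    DifferentialResult,
    GeneSetCollection,
    differential_enrichment,
    filter_gene_set_names,
    gsva_scores,
    select_by_keyword,
    updown_summary,
)
from rteaging.matrix import SampleMatrix
from rteaging.signatures import GeneSignature


def gsva_oracle(X, genes, gene_sets):
    """Literal-loop reimplementation of the three scoring steps.

    Independent of the vectorised implementation: plain Python loops, the
    normal CDF from math.erf, and explicit rank bookkeeping.
    """
    G = len(genes)
    n = len(X[0])
    # step 1: kernel CDF estimates
    h = [[0.0] * n for _ in range(G)]
    for g in range(G):
        mean = sum(X[g]) / n
        var = sum((v - mean) ** 2 for v in X[g]) / (n - 1)
        sd = math.sqrt(var)
        for s in range(n):
            if sd == 0:
                h[g][s] = 0.5
            else:
                bw = sd / 4.0
                total = 0.0
                for k in range(n):
                    z = (X[g][s] - X[g][k]) / bw
                    total += 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
                h[g][s] = total / n
    es = {}
    for set_name, members in gene_sets.items():
        member_idx = {genes.index(m) for m in members}
        m = len(member_idx)
        es[set_name] = []
        for s in range(n):
            # step 2: descending h order, stable in gene index; symmetric weights
            order = sorted(range(G), key=lambda g: (-h[g][s], g))
            rank_of = {g: i + 1 for i, g in enumerate(order)}
            w = {g: abs(G / 2.0 - rank_of[g]) for g in range(G)}
            wsum = sum(w[g] for g in member_idx)
            # step 3: running sum, difference of extremes
            running, max_pos, min_neg = 0.0, 0.0, 0.0
            for g in order:
                if g in member_idx:
                    running += w[g] / wsum
                else:
                    running -= 1.0 / (G - m)
                max_pos = max(max_pos, running)
                min_neg = min(min_neg, running)
            es[set_name].append(max_pos + min_neg)
    return es


class TestNameFiltering:
    def test_direction_suffixed_sets_removed(self):
        assert filter_gene_set_names(["PATH_A_UP", "PATH_B_DN", "PATH_C"]) == ["PATH_C"]

    def test_redundant_listed_sets_removed(self):
        names = [
            "GOBP_POSITIVE_REGULATION_OF_ACUTE_INFLAMMATORY_RESPONSE",
            "HALLMARK_DNA_REPAIR",
        ]
        assert filter_gene_set_names(names) == ["HALLMARK_DNA_REPAIR"]

    def test_keyword_selection_case_insensitive(self):
        names = ["HALLMARK_DNA_REPAIR", "GOBP_INFLAMMATORY_RESPONSE", "KEGG_RIBOSOME"]
        assert select_by_keyword(names, ["inflammatory", "dna_repair"]) == names[:2]


class TestGSVAScores:
    def test_matches_literal_loop_oracle(self, rng):
        G, n = 12, 5
        genes = [f"g{i}" for i in range(G)]
        X = rng.normal(size=(G, n))
        sets = GeneSetCollection(
            [
                GeneSignature.from_genes("S1", genes[:4]),
                GeneSignature.from_genes("S2", genes[4:7]),
            ]
        )
        es = gsva_scores(SampleMatrix(pd.DataFrame(X, index=genes, columns=[f"s{i}" for i in range(n)])), sets)
        oracle = gsva_oracle(X.tolist(), genes, {"S1": genes[:4], "S2": genes[4:7]})
        for name in ("S1", "S2"):
            assert np.allclose(es.loc[name].to_numpy(), oracle[name], atol=1e-10)

    def test_tiny_instance_against_oracle(self):
        # fixed 4-gene, 3-sample instance checked step by step by the oracle
        genes = ["a", "b", "c", "d"]
        X = [
            [1.0, 2.0, 3.0],
            [3.0, 1.0, 2.0],
            [0.5, 0.4, 0.6],
            [2.0, 2.5, 0.1],
        ]
        sets = GeneSetCollection([GeneSignature.from_genes("S", ["a", "b"])])
        es = gsva_scores(
            SampleMatrix(pd.DataFrame(X, index=genes, columns=["s1", "s2", "s3"])), sets
        )
        oracle = gsva_oracle(X, genes, {"S": ["a", "b"]})
        assert np.allclose(es.loc["S"].to_numpy(), oracle["S"])

    def test_extreme_set_and_complement_have_opposite_signs(self, rng):
        # when a half-set occupies the top of the per-sample ranking, its ES is
        # positive and its complement's negative (and vice versa in samples
        # where the pattern flips)
        G, n = 10, 4
        genes = [f"g{i}" for i in range(G)]
        pattern = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.empty((G, n))
        X[:5] = pattern + rng.normal(0, 0.01, size=(5, n))
        X[5:] = -pattern + rng.normal(0, 0.01, size=(5, n))
        sets = GeneSetCollection(
            [
                GeneSignature.from_genes("set_a", genes[:5]),
                GeneSignature.from_genes("set_b", genes[5:]),
            ]
        )
        es = gsva_scores(SampleMatrix(pd.DataFrame(X, index=genes, columns=list("wxyz"))), sets)
        assert (np.sign(es.loc["set_a"]) != np.sign(es.loc["set_b"])).all()
        assert (es.loc["set_a", ["w", "x"]] > 0).all()
        assert (es.loc["set_a", ["y", "z"]] < 0).all()

    def test_duplicated_dataset_duplicates_scores(self, rng):
        G, n = 8, 4
        genes = [f"g{i}" for i in range(G)]
        X = pd.DataFrame(rng.normal(size=(G, n)), index=genes, columns=[f"s{i}" for i in range(n)])
        dup = pd.concat([X, X.add_suffix("_copy", axis=1)], axis=1)
        sets = GeneSetCollection([GeneSignature.from_genes("S", genes[:3])])
        es = gsva_scores(SampleMatrix(dup), sets)
        assert np.allclose(es[[f"s{i}" for i in range(n)]].to_numpy(),
                           es[[f"s{i}_copy" for i in range(n)]].to_numpy())

    def test_zero_spread_gene_handled(self):
        genes = ["flat", "a", "b"]
        X = [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 0.0, 1.0]]
        sets = GeneSetCollection([GeneSignature.from_genes("S", ["a", "b"])])
        es = gsva_scores(SampleMatrix(pd.DataFrame(X, index=genes, columns=list("xyz"))), sets)
        assert np.isfinite(es.to_numpy()).all()

    def test_empty_or_full_intersection_rejected(self, rng):
        genes = ["a", "b", "c"]
        m = SampleMatrix(pd.DataFrame(rng.normal(size=(3, 3)), index=genes, columns=list("xyz")))
        with pytest.raises(ValueError, match="GHOST"):
            gsva_scores(m, GeneSetCollection([GeneSignature.from_genes("GHOST", ["q1", "q2"])]))
        with pytest.raises(ValueError, match="ALL"):
            gsva_scores(m, GeneSetCollection([GeneSignature.from_genes("ALL", genes)]))


def grouping(labels, index):
    return SampleGrouping(pd.Series(labels, index=index), basis="test", mode="median")


class TestDifferentialEnrichment:
    def make_es(self, high_shift, n=12, rng=None):
        rng = rng or np.random.default_rng(0)
        cols = [f"s{i}" for i in range(2 * n)]
        base = rng.normal(0, 0.05, size=(1, 2 * n))
        base[0, n:] += high_shift
        return pd.DataFrame(base, index=["SET"], columns=cols), grouping(
            ["low"] * n + ["high"] * n, cols
        )

    def test_up_call_requires_both_thresholds(self):
        es, grp = self.make_es(0.2)
        res = differential_enrichment(es, grp)
        assert res.table.iloc[0]["call"] == "up"

    def test_small_logfc_is_ns_despite_significance(self):
        es, grp = self.make_es(0.05, n=200)
        res = differential_enrichment(es, grp)
        row = res.table.iloc[0]
        assert row["p"] < 0.05 and row["call"] == "ns"

    def test_identical_groups_are_ns(self):
        cols = [f"s{i}" for i in range(8)]
        es = pd.DataFrame([[0.3] * 8], index=["SET"], columns=cols)
        res = differential_enrichment(es, grouping(["low"] * 4 + ["high"] * 4, cols))
        row = res.table.iloc[0]
        assert row["logFC"] == 0.0 and row["call"] == "ns"

    def test_small_groups_rejected(self):
        cols = ["a", "b", "c"]
        es = pd.DataFrame([[0.1, 0.2, 0.3]], index=["SET"], columns=cols)
        with pytest.raises(ValueError):
            differential_enrichment(es, grouping(["low", "high", "high"], cols))


class TestUpDownSummary:
    def make_result(self, calls, category="dna_repair"):
        table = pd.DataFrame(
            {
                "set": [f"S{i}" for i in range(len(calls))],
                "category": category,
                "logFC": 0.0,
                "p": 1.0,
                "call": calls,
            }
        )
        return DifferentialResult(table)

    def test_signed_count(self):
        res = {"LINE": self.make_result(["up"] * 5 + ["down"] * 2)}
        out = updown_summary(res, categories=("dna_repair",))
        assert out.iloc[0]["up_minus_down"] == 3

    def test_all_ns_gives_zero(self):
        res = {"SINE": self.make_result(["ns"] * 4)}
        out = updown_summary(res, categories=("dna_repair",))
        assert out.iloc[0]["up_minus_down"] == 0

    def test_matches_brute_tally(self, rng):
        calls = list(rng.choice(["up", "down", "ns"], size=30))
        res = {"LTR": self.make_result(calls)}
        out = updown_summary(res, categories=("dna_repair",)).iloc[0]
        assert out["up_minus_down"] == calls.count("up") - calls.count("down")
        assert out["n_up"] == calls.count("up") and out["n_down"] == calls.count("down")
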