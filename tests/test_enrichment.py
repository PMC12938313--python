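"""Ranking, preranked GSEA, ssGSEA, overrepresentation, heatmap ordering."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gbmsynergy.enrichment import (
    EnrichmentError,
    GeneSetCollection,
    RankedGeneList,
    enrichment_score,
    gsea_preranked,
    heatmap_order,
    overrepresentation,
    rank_genes_by_phenotype,
    ssgsea,
)


def make_ranked(n=100, seed=0, scores=None):
    rng = np.random.default_rng(seed)
    s = np.sort(rng.normal(size=n) if scores is None else np.asarray(scores))[::-1]
    genes = np.array([f"g{i:03d}" for i in range(n)], dtype=object)
    return RankedGeneList(genes=genes, scores=s)


class TestRankGenes:
    def _expr(self):
        pheno = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0],
                          index=[f"s{i}" for i in range(5)])
        expr = pd.DataFrame(
            {
                "self": pheno.values,
                "anti": -pheno.values,
                "tied": [10.0, 20.0, 20.0, 30.0, 40.0],
                "flat": [7.0] * 5,
            },
            index=pheno.index,
        ).T
        return expr, pheno

    def test_self_and_anti_correlated_genes_bracket_the_list(self):
        expr, pheno = self._expr()
        ranked = rank_genes_by_phenotype(expr, pheno)
        assert ranked.genes[0] == "self" and ranked.scores[0] == pytest.approx(1.0)
        assert ranked.genes[-1] == "anti" and ranked.scores[-1] == pytest.approx(-1.0)

    def test_midrank_ties_match_hand_computation(self):
        # expression [10,20,20,30,40] -> mid-ranks [1,2.5,2.5,4,5];
        # against phenotype ranks [1..5]: rho = 9.5/sqrt(95)
        expr, pheno = self._expr()
        ranked = rank_genes_by_phenotype(expr, pheno)
        rho = dict(zip(ranked.genes, ranked.scores))["tied"]
        assert rho == pytest.approx(9.5 / math.sqrt(95), abs=1e-12)

    def test_zero_variance_gene_flagged_with_zero_score(self):
        expr, pheno = self._expr()
        ranked = rank_genes_by_phenotype(expr, pheno)
        assert "flat" in ranked.flagged_zero_variance
        assert dict(zip(ranked.genes, ranked.scores))["flat"] == 0.0

    def test_constant_phenotype_rejected(self):
        expr, pheno = self._expr()
        with pytest.raises(EnrichmentError) as exc:
            rank_genes_by_phenotype(expr, pheno * 0 + 1)
        assert exc.value.code == "degenerate-phenotype"


class TestGseaPreranked:
    def test_top_concentrated_set_has_extreme_positive_es(self):
        ranked = make_ranked(100, seed=1)
        es, running, leading = enrichment_score(ranked, ranked.genes[:3], weight=1.0)
        assert es > 0.9
        assert list(leading) == list(ranked.genes[:3])

    def test_running_sum_terminates_at_zero(self):
        ranked = make_ranked(80, seed=2)
        rng = np.random.default_rng(0)
        for size in (5, 17, 40):
            members = rng.choice(ranked.genes, size, replace=False)
            _, running, _ = enrichment_score(ranked, members)
            assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_negating_and_reversing_scores_negates_es(self):
        ranked = make_ranked(60, seed=3)
        flipped = RankedGeneList(genes=ranked.genes[::-1].copy(),
                                 scores=(-ranked.scores[::-1]).copy())
        rng = np.random.default_rng(1)
        members = rng.choice(ranked.genes, 10, replace=False)
        es, _, _ = enrichment_score(ranked, members)
        es_flip, _, _ = enrichment_score(flipped, members)
        assert es_flip == pytest.approx(-es, abs=1e-12)

    def test_es_matches_gseapy_reference(self):
        """Cross-check the weighted running-sum score against gseapy."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(3)
        ranked = make_ranked(50, seed=3, scores=rng.normal(1, 2, 50))
        gs = {"A": list(rng.choice(ranked.genes, 8, replace=False)),
              "B": list(rng.choice(ranked.genes, 12, replace=False))}
        rnk = pd.DataFrame({"gene": ranked.genes, "score": ranked.scores})
        res = gseapy.prerank(rnk=rnk, gene_sets=gs, permutation_num=10,
                             min_size=3, max_size=50, weight=1.0, seed=1,
                             outdir=None, no_plot=True)
        for name, members in gs.items():
            ours, _, _ = enrichment_score(ranked, members, weight=1.0)
            theirs = float(res.res2d.loc[res.res2d.Term == name, "ES"].iloc[0])
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """With 6 genes and a 2-gene set there are only C(6,2)=15 label
        placements; the Monte-Carlo p must agree with exact enumeration."""
        genes = np.array(list("abcdef"), dtype=object)
        scores = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        ranked = RankedGeneList(genes=genes, scores=scores)
        members = ("a", "c")

        def es_unweighted(pos):  # independent running-sum evaluation
            # extreme of the running sum; positive branch wins exact ties
            run, hi, lo = 0.0, -np.inf, np.inf
            for i in range(6):
                run += 1 / 2 if i in pos else -1 / 4
                hi, lo = max(hi, run), min(lo, run)
            return hi if hi >= -lo else lo

        obs = es_unweighted({0, 2})
        all_es = [es_unweighted(set(c)) for c in combinations(range(6), 2)]
        same = [e for e in all_es if e >= 0] if obs >= 0 else [e for e in all_es if e < 0]
        p_exact = sum(abs(e) >= abs(obs) for e in same) / len(same)

        table = gsea_preranked(ranked, GeneSetCollection(sets={"S": members}),
                               weight=0.0, n_perm=4000, seed=0, min_size=2)
        p_mc = table["p"].iloc[0]
        se = math.sqrt(p_exact * (1 - p_exact) / 4000) * 4  # generous MC band
        assert abs(p_mc - p_exact) <= max(se, 0.02)

    def test_null_p_values_approximately_uniform(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            ranked = make_ranked(60, seed=seed)
            sets = {f"S{j}": tuple(rng.choice(ranked.genes, 8, replace=False))
                    for j in range(5)}
            tab = gsea_preranked(ranked, GeneSetCollection(sets=sets),
                                 n_perm=300, seed=seed)
            ps.extend(tab["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_bh_adjustment_is_monotone_and_dominates_p(self):
        rng = np.random.default_rng(9)
        ranked = make_ranked(80, seed=9)
        sets = {f"S{j}": tuple(rng.choice(ranked.genes, 10, replace=False))
                for j in range(8)}
        tab = gsea_preranked(ranked, GeneSetCollection(sets=sets), n_perm=200, seed=9)
        tab = tab.sort_values("p")
        assert (tab["p_adj"].to_numpy() >= tab["p"].to_numpy() - 1e-12).all()
        assert (np.diff(tab["p_adj"].to_numpy()) >= -1e-12).all()

    def test_empty_collection_after_filtering_raises(self):
        ranked = make_ranked(20, seed=4)
        sets = GeneSetCollection(sets={"tiny": ("g000",)})
        with pytest.raises(EnrichmentError) as exc:
            gsea_preranked(ranked, sets)
        assert exc.value.code == "no-testable-sets"


class TestSsgsea:
    def _toy(self):
        expr = pd.DataFrame(
            {"s1": [5.0, 4.0, 3.0, 2.0, 1.0], "s2": [5.0, 4.0, 3.0, 2.0, 1.0]},
            index=[f"g{i}" for i in range(1, 6)],
        )
        sets = GeneSetCollection(sets={"S": ("g1", "g3")})
        return expr, sets

    def test_identical_samples_identical_columns(self):
        expr, sets = self._toy()
        scores = ssgsea(expr, sets, min_size=1)
        assert scores["s1"].iloc[0] == scores["s2"].iloc[0]

    def test_hand_evaluated_weighted_ecdf_difference(self):
        # genes by descending expression: g1,g2,g3,g4,g5 with ranks 5..1;
        # set {g1,g3}, alpha 0.25: running in-set ECDF weighted by rank^alpha,
        # out-of-set ECDF uniform over the 3 non-members.
        expr, sets = self._toy()
        a = 0.25
        w1, w3 = 5.0**a, 3.0**a
        S = w1 + w3
        p_in = [w1 / S, w1 / S, 1.0, 1.0, 1.0]
        p_out = [0.0, 1 / 3, 1 / 3, 2 / 3, 1.0]
        expected = sum(i - o for i, o in zip(p_in, p_out))
        scores = ssgsea(expr, sets, alpha=a, min_size=1)
        assert scores["s1"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.lognormal(1, 1, (30, 4)),
                            index=[f"g{i}" for i in range(30)],
                            columns=list("abcd"))
        sets = GeneSetCollection(
            sets={"S": tuple(expr.index[rng.choice(30, 6, replace=False)])}
        )
        s_raw = ssgsea(expr, sets)
        s_log = ssgsea(np.log2(expr + 1), sets)
        s_sqrt = ssgsea(expr**0.5, sets)
        pd.testing.assert_frame_equal(s_raw, s_log)
        pd.testing.assert_frame_equal(s_raw, s_sqrt)

    def test_moving_set_genes_to_top_increases_score(self):
        rng = np.random.default_rng(6)
        base = pd.Series(rng.lognormal(1, 1, 40), index=[f"g{i}" for i in range(40)])
        sets = GeneSetCollection(sets={"S": tuple(base.index[:8])})
        boosted = base.copy()
        boosted.iloc[:8] = base.max() * np.arange(2, 10)
        lo = ssgsea(base.to_frame("x"), sets)["x"].iloc[0]
        hi = ssgsea(boosted.to_frame("x"), sets)["x"].iloc[0]
        assert hi > lo

    def test_set_covering_all_genes_is_degenerate(self):
        expr, _ = self._toy()
        sets = GeneSetCollection(sets={"ALL": tuple(expr.index)})
        with pytest.raises(EnrichmentError):
            with pytest.warns(UserWarning, match="degenerate-set"):
                ssgsea(expr, sets, min_size=1)


class TestOverrepresentation:
    def _annotation(self, genes, K=10):
        return GeneSetCollection(sets={"T": tuple(genes[:K])})

    def test_matches_hypergeometric_tail_sum(self):
        N, K, n, k = 1000, 10, 50, 5
        background = [f"g{i}" for i in range(N)]
        genes = background[:k] + background[K: K + (n - k)]
        table = overrepresentation(genes, background, self._annotation(background, K))
        row = table.iloc[0]
        assert row["fold_enrichment"] == pytest.approx((k / n) / (K / N))
        p_direct = sum(
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
            for i in range(k, min(K, n) + 1)
        )
        assert row["p"] == pytest.approx(p_direct, rel=1e-9)

    def test_zero_overlap_term_filtered(self):
        background = [f"g{i}" for i in range(100)]
        genes = background[50:60]
        table = overrepresentation(genes, background, self._annotation(background))
        assert table.empty

    def test_list_equal_to_half_background_saturates(self):
        # every term has fold exactly (k/n)/(K/N); a list drawn uniformly as the
        # members themselves gives fold > 1 and survives the filter
        background = [f"g{i}" for i in range(100)]
        table = overrepresentation(background[:10], background,
                                   self._annotation(background))
        assert (table["fold_enrichment"] > 1).all()

    def test_gene_outside_background_rejected(self):
        with pytest.raises(EnrichmentError) as exc:
            overrepresentation(["x"], ["a", "b"], self._annotation(["a", "b"], 2))
        assert exc.value.code == "inconsistent-universe"


class TestHeatmapOrder:
    def test_identical_samples_are_adjacent_leaves(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(10, 4)),
                            index=[f"g{i}" for i in range(10)],
                            columns=list("abcd"))
        expr["d"] = expr["a"]
        hm = heatmap_order(expr, expr.index)
        order = list(hm.samples[hm.col_order])
        assert abs(order.index("a") - order.index("d")) == 1

    def test_planted_blocks_recovered_exactly(self):
        n = 6
        block1 = np.tile([1.0, 1.0, 1.0, -1.0, -1.0, -1.0], (5, 1))
        block2 = -block1
        expr = pd.DataFrame(np.vstack([block1, block2]),
                            index=[f"g{i}" for i in range(10)],
                            columns=[f"s{i}" for i in range(n)])
        hm = heatmap_order(expr, expr.index, n_row_clusters=2)
        labels = hm.row_labels
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_invariant_to_row_permutation(self):
        # the dendrogram is input-order independent up to subtree orientation,
        # so the flat partition (not the leaf sequence) is the invariant
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(12, 5)),
                            index=[f"g{i}" for i in range(12)],
                            columns=[f"s{i}" for i in range(5)])
        hm1 = heatmap_order(expr, expr.index, n_row_clusters=3)
        shuffled = expr.sample(frac=1.0, random_state=0)
        hm2 = heatmap_order(shuffled, shuffled.index, n_row_clusters=3)
        part1 = pd.Series(hm1.row_labels, index=hm1.genes)
        part2 = pd.Series(hm2.row_labels, index=hm2.genes).loc[part1.index]
        # identical partitions up to label renaming
        mapping = {}
        for g in part1.index:
            mapping.setdefault(part1[g], part2[g])
            assert mapping[part1[g]] == part2[g]

    def test_zero_variance_row_dropped_with_warning(self):
        expr = pd.DataFrame(
            {"a": [1.0, 5.0, 2.0], "b": [2.0, 5.0, 4.0], "c": [3.0, 5.0, 1.0]},
            index=["g1", "g2", "g3"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            hm = heatmap_order(expr, expr.index)
        assert "g2" not in hm.genes
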