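import itertools

import numpy as np
import pytest
import scipy.stats

from scplsda.datatypes import GeneSetDB
from scplsda.enrichment import (EnrichmentRecord, RankedList, enrichment_score,
                                filter_fdr, gsea_prerank, keyword_search,
                                remove_redundant)


def brute_force_es(genes, scores, members, weight_exp=1.0):
    """Independent full running-sum evaluation (the oracle)."""
    order = np.lexsort((np.asarray(genes, dtype=str), -np.asarray(scores)))
    genes = np.asarray(genes, dtype=object)[order]
    scores = np.asarray(scores, dtype=float)[order]
    hit = np.isin(genes, list(members))
    n, k = len(genes), hit.sum()
    w = np.abs(scores) ** weight_exp * hit
    w = w / w.sum()
    running = np.cumsum(np.where(hit, w, -1.0 / (n - k)))
    max_pos = float(running.max())
    min_neg = float(min(running.min(), 0.0))
    # ties between the two extremes resolve positive (documented rule)
    return max_pos if max_pos >= -min_neg - 1e-12 else min_neg


def _ranked(n=10, seed=0):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=n)
    scores[scores == 0] = 0.5
    genes = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
    return RankedList(genes=genes, scores=scores)


class TestRankedList:
    def test_sorted_descending_with_symbol_tiebreak(self):
        rl = RankedList(genes=np.array(["b", "a", "c"], dtype=object),
                        scores=np.array([1.0, 1.0, 2.0]))
        assert list(rl.genes) == ["c", "a", "b"]

    def test_duplicates_and_zeros_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RankedList(genes=np.array(["a", "a"], dtype=object),
                       scores=np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="zero"):
            RankedList(genes=np.array(["a", "b"], dtype=object),
                       scores=np.array([1.0, 0.0]))


class TestEnrichmentScore:
    def test_top_two_genes_reach_exactly_one(self):
        rl = RankedList(genes=np.array(list("abcde"), dtype=object),
                        scores=np.array([5.0, 4, 3, 2, 1]))
        assert enrichment_score(rl, frozenset("ab")) == 1.0

    def test_all_three_gene_subsets_match_brute_force(self):
        rl = _ranked(10, seed=1)
        for members in itertools.combinations(rl.genes, 3):
            es = enrichment_score(rl, frozenset(members))
            ref = brute_force_es(rl.genes, rl.scores, members)
            assert es == pytest.approx(ref, abs=1e-12)

    def test_invariant_to_positive_scaling(self):
        rl = _ranked(30, seed=2)
        rl2 = RankedList(genes=rl.genes.copy(), scores=rl.scores * 7.3)
        for members in (frozenset(rl.genes[:4]), frozenset(rl.genes[10:16])):
            assert enrichment_score(rl, members) == \
                pytest.approx(enrichment_score(rl2, members), abs=1e-12)

    def test_negation_symmetry(self):
        """Negating every score (which reverses the list) negates the ES of
        every set."""
        rng = np.random.default_rng(3)
        scores = rng.normal(size=20)
        scores[scores == 0] = 1.0
        genes = np.array([f"g{i}" for i in range(20)], dtype=object)
        rl = RankedList(genes=genes.copy(), scores=scores)
        rl_neg = RankedList(genes=genes.copy(), scores=-scores)
        for seed in range(5):
            r = np.random.default_rng(seed)
            members = frozenset(genes[r.choice(20, 5, replace=False)])
            assert enrichment_score(rl_neg, members) == \
                pytest.approx(-enrichment_score(rl, members), abs=1e-12)


class TestPrerank:
    def test_null_pvalues_uniform(self):
        pvals = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            genes = np.array([f"g{i}" for i in range(120)], dtype=object)
            scores = rng.normal(size=120)
            scores[scores == 0] = 0.3
            rl = RankedList(genes=genes, scores=scores)
            sets = {f"s{i}": ("d", frozenset(
                genes[rng.choice(120, int(rng.integers(5, 25)),
                                 replace=False)]))
                for i in range(20)}
            recs = gsea_prerank(rl, GeneSetDB(sets=sets), n_perm=400,
                                seed=seed + 100)
            pvals += [r.pval for r in recs]
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_set_beats_null_sets(self):
        wins = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            genes = np.array([f"g{i:03d}" for i in range(300)], dtype=object)
            scores = rng.normal(size=300)
            planted = rng.choice(300, 25, replace=False)
            scores[planted] += 2.0
            scores[scores == 0] = 0.3
            rl = RankedList(genes=genes, scores=scores)
            sets = {"signal": ("d", frozenset(genes[planted]))}
            for i in range(10):
                sets[f"null{i}"] = ("d", frozenset(
                    genes[rng.choice(300, 25, replace=False)]))
            recs = {r.set_name: r for r in
                    gsea_prerank(rl, GeneSetDB(sets=sets), n_perm=300,
                                 seed=seed)}
            null_q = np.median([recs[f"null{i}"].fdr_q for i in range(10)])
            wins += recs["signal"].fdr_q < null_q
        assert wins / n_runs >= 0.95

    def test_min_size_and_no_overlap_skipped(self):
        rl = _ranked(20, seed=5)
        sets = {"tiny": ("d", frozenset(rl.genes[:2])),
                "foreign": ("d", frozenset({"zz1", "zz2", "zz3", "zz4",
                                            "zz5"})),
                "ok": ("d", frozenset(rl.genes[:6]))}
        recs = gsea_prerank(rl, GeneSetDB(sets=sets), n_perm=50, seed=0)
        assert [r.set_name for r in recs] == ["ok"]

    def test_deterministic_given_seed(self):
        rl = _ranked(50, seed=6)
        sets = {f"s{i}": ("d", frozenset(rl.genes[i * 5:(i + 1) * 5 + 3]))
                for i in range(5)}
        a = gsea_prerank(rl, GeneSetDB(sets=sets), n_perm=100, seed=4)
        b = gsea_prerank(rl, GeneSetDB(sets=sets), n_perm=100, seed=4)
        assert [(r.set_name, r.es, r.nes, r.pval, r.fdr_q) for r in a] == \
            [(r.set_name, r.es, r.nes, r.pval, r.fdr_q) for r in b]


def _rec(name, nes, genes, q=0.01):
    return EnrichmentRecord(set_name=name, es=np.sign(nes) * 0.5, nes=nes,
                            pval=0.01, fdr_q=q, genes=frozenset(genes),
                            size=len(genes))


class TestFilters:
    def test_fdr_strict_boundary(self):
        recs = [_rec("a", 2.0, {"g1"}, q=0.05), _rec("b", 2.0, {"g2"}, q=0.049)]
        assert [r.set_name for r in filter_fdr(recs, 0.05)] == ["b"]
        assert filter_fdr([], 0.05) == []

    def test_redundancy_boundary_exactly_09_kept(self):
        a = _rec("A", 3.0, {f"g{i}" for i in range(10)})
        b = _rec("B", 2.0, {f"g{i}" for i in range(9)} | {"g11"})  # ratio 0.9
        kept = remove_redundant([a, b], overlap_threshold=0.9)
        assert {r.set_name for r in kept} == {"A", "B"}

    def test_full_overlap_drops_lower_nes(self):
        a = _rec("A", 3.0, {f"g{i}" for i in range(10)})
        b = _rec("B", 2.0, {f"g{i}" for i in range(10)} | {"g11"})  # ratio 1.0
        kept = remove_redundant([a, b], overlap_threshold=0.9)
        assert [r.set_name for r in kept] == ["A"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(40)]
        recs = [_rec(f"s{i:02d}", float(rng.normal()),
                     set(rng.choice(genes, int(rng.integers(3, 12)),
                                    replace=False)))
                for i in range(15)]
        kept = remove_redundant(recs, overlap_threshold=0.6)
        # oracle: independent O(n^2) greedy implementation
        order = sorted(recs, key=lambda r: (-abs(r.nes), r.set_name))
        surv = []
        for rec in order:
            drop = False
            for k in surv:
                shared = len(rec.genes & k.genes)
                if shared / min(len(rec.genes), len(k.genes)) > 0.6:
                    drop = True
                    break
            if not drop:
                surv.append(rec)
        assert [r.set_name for r in kept] == [r.set_name for r in surv]


class TestKeywordSearch:
    def test_substring_and_prefix_wildcard(self):
        recs = {"m1": [_rec("regulation of myelination", 2.0, {"g1"}),
                       _rec("anti-inflammatory response", -1.5, {"g2"})]}
        hits = keyword_search(recs, ["myelin", "inflamm*", "copper"])
        assert set(hits["keyword"]) == {"myelin", "inflamm*"}
        row = hits[hits["keyword"] == "inflamm*"].iloc[0]
        assert row["set_name"] == "anti-inflammatory response"

    def test_no_match_is_empty_not_error(self):
        hits = keyword_search({"m1": [_rec("actin dynamics", 1.0, {"g"})]},
                              ["copper"])
        assert hits.empty


class TestGseapyCrossCheck:
    def test_es_rank_agreement_with_external_tool(self):
        """Independent GSEA implementation (gseapy prerank) produces the
        same enrichment-score ordering on a shared fixture."""
        import pandas as pd
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(0)
        genes = [f"G{i:03d}" for i in range(200)]
        scores = rng.normal(size=200)
        scores[scores == 0] = 0.5
        rl = RankedList(genes=np.array(genes, dtype=object),
                        scores=scores.copy())
        sets = {}
        for i in range(12):
            members = list(np.array(genes)[rng.choice(200, 15,
                                                      replace=False)])
            sets[f"s{i:02d}"] = ("d", frozenset(members))
        mine = {r.set_name: r.es
                for r in gsea_prerank(rl, GeneSetDB(sets=sets), n_perm=100,
                                      seed=0)}
        rnk = pd.DataFrame({"gene": genes, "score": scores}) \
            .sort_values("score", ascending=False)
        res = gseapy.prerank(rnk=rnk,
                             gene_sets={k: sorted(v[1]) for k, v in
                                        sets.items()},
                             permutation_num=50, min_size=3, max_size=500,
                             outdir=None, seed=0, no_plot=True,
                             weight=1.0, threads=1)
        theirs = res.res2d.set_index("Term")["ES"].astype(float)
        common = sorted(set(mine) & set(theirs.index))
        assert len(common) >= 10
        rho = scipy.stats.spearmanr([mine[c] for c in common],
                                    [theirs[c] for c in common]).statistic
        assert rho >= 0.9
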