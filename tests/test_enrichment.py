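"""Fisher / GSEA / PAGE statistics, aggregation and corrections."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from segrules.errors import SegrulesError, ValidationError
from segrules.enrichment import (
    EnrichmentConfig,
    _BatchScorer,
    _RuleScorer,
    aggregate_p,
    correct_bonferroni,
    correct_fdr,
    correct_permutation,
    fisher_enrichment,
    gsea_p,
    gsea_score,
    page_p,
    score_rules,
)
from segrules.search import Literal, Rule, TERM

from conftest import ranked_from_scores


def make_ranked(n, logfc=None):
    logfc = logfc if logfc is not None else [0.0] * n
    return ranked_from_scores(
        [(f"g{i}", n - i, logfc[i]) for i in range(n)]
    )


def hypergeom_tail_oracle(x, n, k, m):
    """Exact integer-arithmetic P(X >= x) for overlap of m draws with K marks."""
    total = math.comb(n, m)
    acc = 0
    for i in range(x, min(m, k) + 1):
        acc += math.comb(k, i) * math.comb(n - k, m - i)
    return acc / total


def gsea_walk_oracle(hits, n):
    """Brute-force running sum; returns (max deviation, min deviation)."""
    m = len(hits)
    inc, dec = 1 / m, 1 / (n - m)
    s, smax, smin = 0.0, 0.0, 0.0
    for pos in range(n):
        s += inc if pos in hits else -dec
        smax, smin = max(smax, s), min(smin, s)
    return smax, smin


class TestFisher:
    def test_disjoint_from_top_is_one(self):
        ranked = make_ranked(20)
        p = fisher_enrichment({"g15", "g16"}, ranked, top_k=10)
        assert p == pytest.approx(1.0)

    def test_exact_match_of_top_block(self):
        ranked = make_ranked(20)
        p = fisher_enrichment({f"g{i}" for i in range(10)}, ranked, top_k=10)
        assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-12)
        assert p == pytest.approx(5.4126e-6, rel=1e-4)

    def test_four_of_five_universe_ten(self):
        ranked = make_ranked(10)
        p = fisher_enrichment({f"g{i}" for i in range(4)}, ranked, top_k=5)
        assert p == pytest.approx(1 / 42, rel=1e-12)

    @pytest.mark.parametrize("n", [5, 12, 25])
    def test_matches_exact_oracle(self, n):
        ranked = make_ranked(n)
        for k in range(1, n):
            for m in range(1, n + 1):
                for x in range(max(0, m - (n - k)), min(m, k) + 1):
                    genes = {f"g{i}" for i in range(x)} | {
                        f"g{n - 1 - i}" for i in range(m - x)
                    }
                    assert len(genes) == m
                    p = fisher_enrichment(genes, ranked, top_k=k)
                    assert p == pytest.approx(
                        hypergeom_tail_oracle(x, n, k, m), abs=1e-12
                    )

    def test_empty_rule_rejected(self):
        with pytest.raises(SegrulesError):
            fisher_enrichment(set(), make_ranked(10), top_k=5)


class TestGseaScore:
    def test_top_gene_scores_one(self):
        assert gsea_score({"g0"}, make_ranked(4)) == pytest.approx(1.0)

    def test_bottom_gene_scores_minus_one(self):
        assert gsea_score({"g3"}, make_ranked(4)) == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", [4, 8, 10])
    def test_all_subsets_match_walk_oracle(self, n):
        ranked = make_ranked(n)
        for r in range(1, n):
            for hits in itertools.combinations(range(n), r):
                genes = {f"g{i}" for i in hits}
                got = gsea_score(genes, ranked)
                smax, smin = gsea_walk_oracle(set(hits), n)
                expected = smax if smax >= -smin else smin
                if abs(smax + smin) < 1e-9:  # magnitude tie: either sign valid
                    assert abs(got) == pytest.approx(abs(expected), abs=1e-12)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)
                assert abs(got) <= 1.0

    def test_degenerate_sets_rejected(self):
        ranked = make_ranked(5)
        with pytest.raises(SegrulesError):
            gsea_score(set(), ranked)
        with pytest.raises(SegrulesError):
            gsea_score({f"g{i}" for i in range(5)}, ranked)


class TestGseaP:
    def test_extreme_top_set_is_significant(self):
        ranked = make_ranked(100)
        p = gsea_p({f"g{i}" for i in range(5)}, ranked, n_perm=199, seed=3)
        assert p <= 0.05

    def test_add_one_lower_bound_and_determinism(self):
        ranked = make_ranked(30)
        genes = {"g0", "g5", "g20"}
        p1 = gsea_p(genes, ranked, n_perm=99, seed=7)
        p2 = gsea_p(genes, ranked, n_perm=99, seed=7)
        assert p1 == p2 >= 1 / 100

    def test_weak_set_is_not_significant(self):
        # evenly spread hits: tiny |ES|, null beats it almost always
        ranked = make_ranked(40)
        genes = {f"g{i}" for i in range(1, 40, 8)}
        p = gsea_p(genes, ranked, n_perm=99, seed=1)
        assert p > 0.3


class TestPageP:
    def test_central_case(self):
        logfc = [1.0, -1.0, 1.0, -1.0, 0.0, 0.0]
        ranked = make_ranked(6, logfc)
        p = page_p({"g4", "g5"}, ranked)  # set mean 0 == global mean 0
        assert p == pytest.approx(1.0)

    def test_z_two_example(self):
        # global scores mean 0, sd 1 (ddof=1); a 4-gene set with mean ~1
        # should give z ~ 2 and two-sided p ~ 0.0455
        rng = np.random.default_rng(0)
        bg = rng.normal(size=2000)
        bg = (bg - bg.mean()) / bg.std(ddof=1)  # exactly mu=0, sd=1
        logfc = list(bg) + [1.0] * 4
        # recentre/scale again so the whole list has mu=0, sd=1
        arr = np.array(logfc)
        arr = (arr - arr.mean()) / arr.std(ddof=1)
        n = len(arr)
        ranked = make_ranked(n, list(arr))
        genes = {f"g{i}" for i in range(n)}
        # pick a 4-gene set whose mean is ~1 after the rescale
        target = sorted(range(n), key=lambda i: abs(arr[i] - 1.0))[:4]
        sel = {f"g{i}" for i in target}
        sm = arr[target].mean()
        z = sm * math.sqrt(4)
        expected = 2 * (1 - norm.cdf(abs(z)))
        assert page_p(sel, ranked) == pytest.approx(expected, abs=1e-12)

    def test_whole_universe_is_central(self):
        logfc = [0.5, -0.3, 0.7, 0.1]
        ranked = make_ranked(4, logfc)
        p = page_p({f"g{i}" for i in range(4)}, ranked)
        assert p == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        logfc = list(rng.normal(size=50))
        genes = {f"g{i}" for i in range(7)}
        p1 = page_p(genes, make_ranked(50, logfc))
        p2 = page_p(genes, make_ranked(50, [3.5 * v - 2.0 for v in logfc]))
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_degenerate_scores_rejected(self):
        ranked = make_ranked(5, [1.0] * 5)
        with pytest.raises(SegrulesError):
            page_p({"g0"}, ranked)


class TestAggregate:
    def test_equal_weights_mean(self):
        assert aggregate_p((0.1, 0.2, 0.3), (1, 1, 1)) == pytest.approx(0.2)

    def test_weighted(self):
        assert aggregate_p((0.1, 0.2, 0.3), (2, 1, 1)) == pytest.approx(0.175)

    def test_single_test_degeneracy(self):
        assert aggregate_p((0.42, None, None), (1, 0, 0)) == 0.42

    def test_bounded_by_min_and_max(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            ps = rng.random(3)
            ws = rng.random(3)
            if ws.sum() == 0:
                continue
            agg = aggregate_p(tuple(ps), tuple(ws))
            assert ps.min() - 1e-12 <= agg <= ps.max() + 1e-12

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_p((0.1, 0.2, 0.3), (0, 0, 0))


def scored_rules(n_rules, n_genes, seed=0, set_size=6):
    rng = np.random.default_rng(seed)
    ranked = make_ranked(n_genes, list(rng.normal(size=n_genes)))
    rules = []
    for i in range(n_rules):
        genes = rng.choice(n_genes, size=set_size, replace=False)
        rules.append(
            Rule(
                literals=(Literal(TERM, f"T{i}"),),
                covered=frozenset(f"g{j}" for j in genes),
            )
        )
    return ranked, rules


class TestCorrections:
    def test_single_rule_raw_equals_corrected(self):
        ranked, rules = scored_rules(1, 30)
        cfg = EnrichmentConfig(top_k=10, gsea_permutations=50, seed=0)
        score_rules(rules, ranked, cfg)
        raw = rules[0].p_aggregate
        assert correct_bonferroni(rules).rules[0].p_corrected == pytest.approx(raw)
        assert correct_fdr(rules).rules[0].p_corrected == pytest.approx(raw)

    def test_bonferroni_multiplies_by_family_size(self):
        rules = [
            Rule((Literal(TERM, f"T{i}"),), frozenset({"g"}), p_aggregate=p)
            for i, p in enumerate([0.01, 0.02, 0.03])
        ]
        out = correct_bonferroni(rules)
        assert [r.p_corrected for r in out.rules] == pytest.approx([0.03, 0.06, 0.09])

    def test_bh_step_up(self):
        rules = [
            Rule((Literal(TERM, f"T{i}"),), frozenset({"g"}), p_aggregate=p)
            for i, p in enumerate([0.01, 0.02, 0.03])
        ]
        out = correct_fdr(rules)
        assert [r.p_corrected for r in out.rules] == pytest.approx([0.03, 0.03, 0.03])

    def test_bh_matches_statsmodels_and_is_monotone(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        ps = rng.random(25)
        rules = [
            Rule((Literal(TERM, f"T{i}"),), frozenset({"g"}), p_aggregate=float(p))
            for i, p in enumerate(ps)
        ]
        out = correct_fdr(rules)
        expected = sorted(multipletests(ps, method="fdr_bh")[1])
        got = [r.p_corrected for r in out.rules]
        assert got == pytest.approx(expected)
        assert all(a <= b + 1e-15 for a, b in zip(got, got[1:]))

    def test_permutation_bounds_and_sorting(self):
        ranked, rules = scored_rules(8, 40, seed=3)
        cfg = EnrichmentConfig(
            top_k=10, gsea_permutations=50, n_permutations=49, seed=3
        )
        score_rules(rules, ranked, cfg)
        result = correct_permutation(rules, ranked, cfg)
        assert len(result.null_best_p) == 49
        ps = [r.p_corrected for r in result.rules]
        assert all(1 / 50 <= p <= 1.0 for p in ps)
        assert ps == sorted(ps)

    def test_rule_beaten_by_every_permutation_gets_one(self):
        ranked, rules = scored_rules(5, 40, seed=4)
        cfg = EnrichmentConfig(
            top_k=10, gsea_permutations=50, n_permutations=49, seed=4
        )
        score_rules(rules, ranked, cfg)
        # force one rule's aggregate above any possible null minimum
        rules[0].p_aggregate = 1.0
        result = correct_permutation(rules, ranked, cfg)
        worst = max(result.rules, key=lambda r: r.p_aggregate)
        assert worst.p_corrected == pytest.approx(1.0)

    def test_corrected_at_least_raw_on_null(self):
        ranked, rules = scored_rules(10, 60, seed=5)
        cfg = EnrichmentConfig(
            top_k=15, gsea_permutations=50, n_permutations=99, seed=5
        )
        score_rules(rules, ranked, cfg)
        result = correct_permutation(rules, ranked, cfg)
        # maxT corrected p dominates the raw aggregate for the minimum rule
        best = result.rules[0]
        assert best.p_corrected >= min(1.0, best.p_aggregate)


class TestBatchScalarConsistency:
    def test_batch_equals_scalar_path(self):
        ranked, rules = scored_rules(12, 50, seed=6)
        cfg = EnrichmentConfig(top_k=12, gsea_permutations=40, seed=6)
        batch = _BatchScorer(rules, ranked, cfg)
        pf, pg, pp, pa = batch.score(None)
        scorer = batch.inner
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(ranked))
        posmap = np.empty(len(ranked), dtype=np.int64)
        posmap[perm] = np.arange(len(ranked))
        pf2, pg2, pp2, pa2 = batch.score(posmap)
        genes = ranked.genes
        pos = {genes[perm[i]]: i for i in range(len(genes))}
        for i, rule in enumerate(rules):
            s_id = scorer.score_rule(rule.covered, scorer.identity_pos)
            s_pm = scorer.score_rule(rule.covered, pos)
            for got, want in zip((pf[i], pg[i], pp[i], pa[i]), s_id):
                assert got == pytest.approx(want, abs=1e-12)
            for got, want in zip((pf2[i], pg2[i], pp2[i], pa2[i]), s_pm):
                assert got == pytest.approx(want, abs=1e-12)

    def test_public_functions_agree_with_scorer(self):
        ranked, rules = scored_rules(5, 30, seed=8)
        cfg = EnrichmentConfig(top_k=8, gsea_permutations=60, seed=8)
        score_rules(rules, ranked, cfg)
        for rule in rules:
            assert rule.p_fisher == pytest.approx(
                fisher_enrichment(rule.covered, ranked, 8), abs=1e-12
            )
            assert rule.p_page == pytest.approx(page_p(rule.covered, ranked), abs=1e-12)

    def test_zero_weight_skips_test(self):
        ranked, rules = scored_rules(3, 30, seed=9)
        cfg = EnrichmentConfig(top_k=8, weights=(1.0, 0.0, 0.0), seed=9)
        score_rules(rules, ranked, cfg)
        for rule in rules:
            assert rule.p_gsea is None and rule.p_page is None
            assert rule.p_aggregate == pytest.approx(rule.p_fisher)
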