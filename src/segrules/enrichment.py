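"""Enrichment scoring of candidate rules and multiple-testing correction.

Each rule's gene set is scored on a ranked gene list with three tests:

* Fisher's exact test — one-sided over-representation of the rule's genes
  among the top-k ranked genes (hypergeometric tail),
* GSEA — classic unweighted running-sum enrichment score with an empirical
  permutation p-value,
* PAGE — z-test of the rule genes' mean logFC against the global logFC
  distribution.

The three p-values combine into a weighted arithmetic mean (a ranking
heuristic, not a calibrated probability), and family-wise significance is
assessed by gene-label permutation (maxT construction over the minimum
aggregate p), or alternatively by Bonferroni or Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import SegrulesError, ValidationError
from .preprocess import RankedGeneList
from .search import Rule


@dataclass
class EnrichmentConfig:
    """Parameters of the scoring and correction stage.

    top_k defines the "differentially expressed" cut for Fisher's test
    (the remainder of the ranked list is the background); weights order is
    (Fisher, GSEA, PAGE), equal by default.
    """

    top_k: int = 1000
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gsea_permutations: int = 200
    correction: str = "permutation"  # permutation | bonferroni | fdr
    n_permutations: int = 99
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.weights = tuple(float(w) for w in self.weights)
        if not any(w > 0 for w in self.weights) or any(w < 0 for w in self.weights):
            raise ValidationError("weights must be non-negative with at least one > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.correction not in ("permutation", "bonferroni", "fdr"):
            raise ValidationError(f"unknown correction {self.correction!r}")


@dataclass
class EnrichmentResult:
    """Scored rules sorted by corrected then aggregate p, plus the
    permutation null (per-permutation minimum aggregate p) when available."""

    rules: list[Rule]
    null_best_p: list[float] | None = None

    def significant(self, alpha: float) -> list[Rule]:
        return [r for r in self.rules if r.p_corrected is not None and r.p_corrected <= alpha]


# -- individual tests ------------------------------------------------------

def fisher_enrichment(
    rule_genes: Iterable[str], ranked: RankedGeneList, top_k: int
) -> float:
    """One-sided hypergeometric tail P(X >= overlap with the top-k genes)."""
    genes = frozenset(rule_genes)
    if not genes:
        raise SegrulesError("Fisher test on an empty gene set")
    universe = ranked.genes
    n = len(universe)
    if not 0 < top_k < n:
        raise ValidationError(f"top_k={top_k} must be in 1..{n - 1}")
    missing = genes - set(universe)
    if missing:
        raise ValidationError(f"rule genes outside ranked universe: {sorted(missing)[:5]}")
    x = len(genes & set(universe[:top_k]))
    return float(hypergeom.sf(x - 1, n, top_k, len(genes)))


def _es_from_positions(positions: Sequence[int], n: int) -> float:
    """Classic GSEA enrichment score from sorted 0-based hit positions.

    The running sum gains 1/m at each hit and loses 1/(n-m) at each miss;
    the signed deviation of maximal absolute value is returned (ties between
    the positive and negative extreme resolve to the positive one).
    """
    m = len(positions)
    inc, dec = 1.0 / m, 1.0 / (n - m)
    best_max, best_min = 0.0, 0.0
    for i, p in enumerate(positions):
        before = i * inc - (p - i) * dec
        after = before + inc
        if after > best_max:
            best_max = after
        if before < best_min:
            best_min = before
    return best_max if best_max >= -best_min else best_min


def gsea_score(rule_genes: Iterable[str], ranked: RankedGeneList) -> float:
    """Classic (unweighted) GSEA enrichment score of a gene set."""
    genes = frozenset(rule_genes)
    n = len(ranked)
    positions = sorted(i for i, g in enumerate(ranked.genes) if g in genes)
    if not positions or len(positions) >= n:
        raise SegrulesError("GSEA needs a non-empty proper subset of the ranked genes")
    return _es_from_positions(positions, n)


def gsea_p(
    rule_genes: Iterable[str], ranked: RankedGeneList, n_perm: int, seed: int
) -> float:
    """Empirical two-sided GSEA p-value over gene-label shuffles.

    p = (r + 1) / (n_perm + 1) where r counts permutations whose |ES|
    reaches the observed |ES| (add-one rule: never returns zero).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    genes = frozenset(rule_genes)
    n = len(ranked)
    m = len(genes & set(ranked.genes))
    observed = abs(gsea_score(genes, ranked))
    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_perm):
        positions = np.sort(rng.choice(n, size=m, replace=False))
        if abs(_es_from_positions(positions.tolist(), n)) >= observed:
            r += 1
    return (r + 1) / (n_perm + 1)


def page_p(rule_genes: Iterable[str], ranked: RankedGeneList) -> float:
    """Parametric gene-set test: z-score of the set's mean logFC.

    z = (Sm - mu) * sqrt(m) / delta with mu, delta the mean and standard
    deviation of all gene-level logFC values; two-sided normal tail.
    """
    genes = frozenset(rule_genes)
    if not genes:
        raise SegrulesError("PAGE on an empty gene set")
    lfc = ranked.logfc
    scores = np.array([e.logfc for e in ranked.entries])
    mu = scores.mean()
    delta = scores.std(ddof=1)
    if delta == 0:
        raise SegrulesError("degenerate gene-level scores (zero standard deviation)")
    member = [lfc[g] for g in genes if g in lfc]
    if not member:
        raise ValidationError("no rule gene present in the ranked list")
    z = (np.mean(member) - mu) * math.sqrt(len(member)) / delta
    return float(math.erfc(abs(z) / math.sqrt(2)))


def aggregate_p(
    p_values: Sequence[float | None], weights: Sequence[float]
) -> float:
    """Weighted arithmetic mean of per-test p-values.

    Entries with weight 0 are skipped and may be None (test not run).
    """
    num = den = 0.0
    for p, w in zip(p_values, weights):
        if w < 0:
            raise ValidationError("weights must be non-negative")
        if w == 0:
            continue
        if p is None:
            raise ValidationError("missing p-value for a positively weighted test")
        if not 0 <= p <= 1:
            raise ValidationError(f"p-value {p} outside [0, 1]")
        num += w * p
        den += w
    if den == 0:
        raise ValidationError("at least one weight must be positive")
    return num / den


# -- fast shared machinery for scoring and permutation rescoring -----------

class _GseaNull:
    """Seeded sample of the null |ES| distribution, cached per set size.

    Under gene-label shuffling the hit positions of a size-m set are a
    uniform random m-subset of the n ranks, so the null depends only on
    (n, m); one shared sample per size serves every rule and permutation.
    """

    def __init__(self, n: int, n_perm: int, seed_seq: np.random.SeedSequence):
        self.n = n
        self.n_perm = n_perm
        self._seed_seq = seed_seq
        self._cache: dict[int, np.ndarray] = {}

    def abs_es_sample(self, m: int) -> np.ndarray:
        if m not in self._cache:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=self._seed_seq.entropy, spawn_key=(9000, m)
                )
            )
            vals = np.empty(self.n_perm)
            for i in range(self.n_perm):
                pos = np.sort(rng.choice(self.n, size=m, replace=False))
                vals[i] = abs(_es_from_positions(pos.tolist(), self.n))
            vals.sort()
            self._cache[m] = vals
        return self._cache[m]

    def p_value(self, observed_es: float, m: int) -> float:
        null = self.abs_es_sample(m)
        r = int(len(null) - np.searchsorted(null, abs(observed_es), side="left"))
        return (r + 1) / (self.n_perm + 1)


class _RuleScorer:
    """Scores rule gene sets against a (possibly gene-permuted) ranked list."""

    def __init__(self, ranked: RankedGeneList, cfg: EnrichmentConfig):
        self.cfg = cfg
        self.n = len(ranked)
        if not 0 < cfg.top_k < self.n:
            raise ValidationError(
                f"top_k={cfg.top_k} must be below the ranked universe size {self.n}"
            )
        self.genes = np.array(ranked.genes)
        self.logfc = np.array([e.logfc for e in ranked.entries])
        self.mu = float(self.logfc.mean())
        self.delta = float(self.logfc.std(ddof=1))
        if self.delta == 0:
            raise SegrulesError("degenerate gene-level scores (zero standard deviation)")
        seed_seq = np.random.SeedSequence(cfg.seed)
        self.gsea_null = _GseaNull(self.n, cfg.gsea_permutations, seed_seq)
        self._fisher_tail: dict[int, np.ndarray] = {}
        self.identity_pos = {g: i for i, g in enumerate(ranked.genes)}

    def fisher_tail(self, m: int) -> np.ndarray:
        # sf table over possible overlap counts x = 0..m for set size m
        if m not in self._fisher_tail:
            x = np.arange(0, m + 1)
            self._fisher_tail[m] = hypergeom.sf(x - 1, self.n, self.cfg.top_k, m)
        return self._fisher_tail[m]

    def score_rule(
        self, covered: frozenset[str], pos: dict[str, int]
    ) -> tuple[float | None, float | None, float | None, float]:
        """(p_fisher, p_gsea, p_page, p_aggregate) of one gene set under the
        gene->rank assignment ``pos``."""
        wf, wg, wp = self.cfg.weights
        idx = sorted(pos[g] for g in covered)
        m = len(idx)
        if m == 0 or m >= self.n:
            raise SegrulesError("rule gene set must be a non-empty proper subset")
        p_fisher = p_gsea = p_page = None
        if wf > 0:
            x = bisect_left(idx, self.cfg.top_k)
            p_fisher = float(self.fisher_tail(m)[x])
        if wg > 0:
            es = _es_from_positions(idx, self.n)
            p_gsea = self.gsea_null.p_value(es, m)
        if wp > 0:
            sm = float(self.logfc[idx].mean())
            z = (sm - self.mu) * math.sqrt(m) / self.delta
            p_page = float(math.erfc(abs(z) / math.sqrt(2)))
        p_agg = aggregate_p((p_fisher, p_gsea, p_page), self.cfg.weights)
        return p_fisher, p_gsea, p_page, p_agg


class _BatchScorer:
    """Vectorized scoring of a fixed rule collection under rank permutations.

    Rule gene sets are flattened into one index array with segment
    boundaries; each permutation then costs a handful of numpy segment
    operations (reduceat) instead of a per-rule Python loop.  Results are
    bit-identical to the scalar per-rule path.
    """

    def __init__(self, rules: list[Rule], ranked: RankedGeneList, cfg: EnrichmentConfig):
        self.inner = _RuleScorer(ranked, cfg)
        self.cfg = cfg
        n = self.inner.n
        pos0 = self.inner.identity_pos
        for rule in rules:
            missing = rule.covered - pos0.keys()
            if missing:
                raise ValidationError(
                    f"rule genes outside ranked universe: {sorted(missing)[:5]}"
                )
            if not 0 < len(rule.covered) < n:
                raise SegrulesError("rule gene set must be a non-empty proper subset")
        self.m_arr = np.array([len(r.covered) for r in rules])
        self.starts = np.concatenate([[0], np.cumsum(self.m_arr)[:-1]]).astype(np.int64)
        self.flat = np.concatenate(
            [np.fromiter((pos0[g] for g in r.covered), dtype=np.int64) for r in rules]
        )
        self.seg_id = np.repeat(np.arange(len(rules)), self.m_arr)
        self.i_local = np.arange(len(self.flat)) - self.starts[self.seg_id]
        self.inc = 1.0 / self.m_arr[self.seg_id]
        self.dec = 1.0 / (n - self.m_arr)[self.seg_id]
        self.seg_base = self.seg_id * n  # sort key offset per segment
        # group rules by set size for null-table lookups
        self.by_m: dict[int, np.ndarray] = {}
        for i, m in enumerate(self.m_arr):
            self.by_m.setdefault(int(m), []).append(i)
        self.by_m = {m: np.array(ix) for m, ix in self.by_m.items()}

    def score(self, posmap: np.ndarray | None = None):
        """p arrays (fisher, gsea, page, aggregate) for one gene->rank map.

        ``posmap[j]`` is the rank of the gene originally at rank j; None
        means the identity (observed data).
        """
        from scipy.special import erfc

        inner, cfg = self.inner, self.cfg
        n = inner.n
        wf, wg, wp = cfg.weights
        pos = self.flat if posmap is None else posmap[self.flat]
        p_fisher = p_gsea = p_page = None
        if wf > 0:
            x = np.add.reduceat(pos < cfg.top_k, self.starts)
            p_fisher = np.empty(len(self.m_arr))
            for m, ix in self.by_m.items():
                p_fisher[ix] = inner.fisher_tail(m)[x[ix]]
        if wg > 0:
            key = np.sort(self.seg_base + pos)
            pos_sorted = key - self.seg_base
            before = self.i_local * self.inc - (pos_sorted - self.i_local) * self.dec
            after = before + self.inc
            best_max = np.maximum(np.maximum.reduceat(after, self.starts), 0.0)
            best_min = np.minimum(np.minimum.reduceat(before, self.starts), 0.0)
            es = np.where(best_max >= -best_min, best_max, best_min)
            p_gsea = np.empty(len(self.m_arr))
            B = cfg.gsea_permutations
            for m, ix in self.by_m.items():
                null = inner.gsea_null.abs_es_sample(m)
                r = len(null) - np.searchsorted(null, np.abs(es[ix]), side="left")
                p_gsea[ix] = (r + 1) / (B + 1)
        if wp > 0:
            sums = np.add.reduceat(inner.logfc[pos], self.starts)
            sm = sums / self.m_arr
            z = (sm - inner.mu) * np.sqrt(self.m_arr) / inner.delta
            p_page = erfc(np.abs(z) / math.sqrt(2))
        num = np.zeros(len(self.m_arr))
        den = 0.0
        for p, w in ((p_fisher, wf), (p_gsea, wg), (p_page, wp)):
            if w > 0:
                num += w * p
                den += w
        return p_fisher, p_gsea, p_page, num / den


def score_rules(
    rules: list[Rule], ranked: RankedGeneList, cfg: EnrichmentConfig
) -> list[Rule]:
    """Set p_fisher/p_gsea/p_page/p_aggregate on every rule (in place)."""
    if not rules:
        return rules
    batch = _BatchScorer(rules, ranked, cfg)
    pf, pg, pp, pa = batch.score(None)
    for i, rule in enumerate(rules):
        rule.p_fisher = None if pf is None else float(pf[i])
        rule.p_gsea = None if pg is None else float(pg[i])
        rule.p_page = None if pp is None else float(pp[i])
        rule.p_aggregate = float(pa[i])
    return rules


def _sorted_result(rules: list[Rule], null_best_p=None) -> EnrichmentResult:
    order = sorted(
        range(len(rules)),
        key=lambda i: (rules[i].p_corrected, rules[i].p_aggregate, i),
    )
    return EnrichmentResult(rules=[rules[i] for i in order], null_best_p=null_best_p)


# -- corrections -----------------------------------------------------------

def correct_permutation(
    rules: list[Rule],
    ranked: RankedGeneList,
    cfg: EnrichmentConfig,
    scorer: Callable[[frozenset[str], dict[str, int]], tuple] | None = None,
) -> EnrichmentResult:
    """Family-wise permutation correction (maxT over the aggregate p).

    For each of ``cfg.n_permutations`` seeded gene-label shuffles of the
    ranked list, every rule is rescored with the full per-rule procedure and
    the minimum aggregate p over rules is recorded; then
    p_corrected(rule) = (#{null minima <= p_aggregate(rule)} + 1) / (B + 1).
    """
    if not rules:
        return EnrichmentResult(rules=[], null_best_p=[])
    if any(r.p_aggregate is None for r in rules):
        raise ValidationError("rules must be scored before permutation correction")
    batch = _BatchScorer(rules, ranked, cfg) if scorer is None else None
    internal = batch.inner if batch is not None else _RuleScorer(ranked, cfg)
    n = internal.n
    genes = list(internal.genes)
    null_best: list[float] = []
    for b in range(cfg.n_permutations):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, b))
        )
        perm = rng.permutation(n)
        if batch is not None:
            posmap = np.empty(n, dtype=np.int64)
            posmap[perm] = np.arange(n)
            _pf, _pg, _pp, p_agg = batch.score(posmap)
            best = float(p_agg.min())
        else:
            pos = {genes[perm[i]]: i for i in range(n)}
            best = math.inf
            for rule in rules:
                _pf, _pg, _pp, p_agg = scorer(rule.covered, pos)
                if p_agg < best:
                    best = p_agg
        null_best.append(best)
    null_sorted = sorted(null_best)
    B = cfg.n_permutations
    for rule in rules:
        r = _count_leq(null_sorted, rule.p_aggregate)
        rule.p_corrected = (r + 1) / (B + 1)
    return _sorted_result(rules, null_best_p=null_best)


def _count_leq(sorted_vals: list[float], x: float) -> int:
    import bisect

    return bisect.bisect_right(sorted_vals, x)


def correct_bonferroni(rules: list[Rule]) -> EnrichmentResult:
    """Bonferroni family-wise correction: p_corrected = min(1, m * p)."""
    _require_scored(rules)
    m = len(rules)
    for rule in rules:
        rule.p_corrected = min(1.0, m * rule.p_aggregate)
    return _sorted_result(rules)


def correct_fdr(rules: list[Rule]) -> EnrichmentResult:
    """Benjamini-Hochberg step-up adjusted aggregate p-values."""
    _require_scored(rules)
    if not rules:
        return EnrichmentResult(rules=[])
    ps = [r.p_aggregate for r in rules]
    adjusted = multipletests(ps, method="fdr_bh")[1]
    for rule, q in zip(rules, adjusted):
        rule.p_corrected = float(q)
    return _sorted_result(rules)


def _require_scored(rules: list[Rule]) -> None:
    if any(r.p_aggregate is None for r in rules):
        raise ValidationError("rules must carry aggregate p-values")
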