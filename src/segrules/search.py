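"""Conjunctive rule search over the ontology hierarchy.

The hypothesis language: a rule is a conjunction of at most one TERM literal
per branch (BP, MF, CC, KEGG) plus at most one INT literal wrapping a single
term from any enabled branch.  A TERM literal covers the term's propagated
gene set; an INT literal covers the interaction closure of that set.  The
rule's extension is the intersection of its literals' gene sets, restricted
to the annotation universe.

Search proceeds by top-down, level-wise refinement: terms are visited
parents-before-children within each slot and conjunctions shortest-first,
and a conjunction whose extension falls below ``min_set_size`` is pruned
together with every specialization (replacing a term by a descendant or
appending literals can only shrink the extension).  A conjunction is only
evaluated once all of its one-step generalizations are known viable, so no
specialization of a pruned conjunction is ever scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .errors import SegrulesError, ValidationError
from .ontology import BRANCHES, AnnotationSet, InteractionDB, Ontology, interacting_set

TERM = "TERM"
INT = "INT"


class Literal(NamedTuple):
    """One conjunct: a bare ontology term or its interaction closure."""

    kind: str  # TERM or INT
    term: str


@dataclass
class Rule:
    """A conjunction of literals together with its covered gene set and p-values."""

    literals: tuple[Literal, ...]
    covered: frozenset[str]
    p_fisher: float | None = None
    p_gsea: float | None = None
    p_page: float | None = None
    p_aggregate: float | None = None
    p_corrected: float | None = None

    @property
    def n_genes(self) -> int:
        return len(self.covered)

    def describe(self, names: dict[str, str] | None = None) -> str:
        """Human-readable conjunction, INT rendered as 'interacting with'."""
        names = names or {}
        parts = []
        for lit in self.literals:
            label = names.get(lit.term, lit.term)
            parts.append(f"interacting with {label}" if lit.kind == INT else label)
        return " ∧ ".join(parts)


@dataclass
class SearchParams:
    """Bounds on the hypothesis language.

    min_set_size drives anti-monotone pruning; max_set_size (optional) only
    filters output — a too-large extension may still shrink into range under
    specialization, so its specializations are kept.
    """

    min_set_size: int = 1
    max_set_size: int | None = None
    max_literals: int = 4
    branches_enabled: tuple[str, ...] = BRANCHES
    allow_int: bool = True

    def __post_init__(self):
        if self.min_set_size < 1:
            raise ValidationError("min_set_size must be >= 1")
        if not 1 <= self.max_literals <= 5:
            raise ValidationError("max_literals must be in 1..5")
        bad = set(self.branches_enabled) - set(BRANCHES)
        if bad:
            raise ValidationError(f"unknown branches: {sorted(bad)}")
        # normalize to canonical order
        self.branches_enabled = tuple(
            b for b in BRANCHES if b in self.branches_enabled
        )


@dataclass
class SearchStats:
    """Instrumentation of a search run."""

    n_evaluated: int = 0
    n_pruned: int = 0
    n_emitted: int = 0
    record: bool = False
    evaluated: list[tuple[Literal, ...]] = field(default_factory=list)
    pruned: list[tuple[Literal, ...]] = field(default_factory=list)


def evaluate_rule(
    literals: Iterable[Literal], ann: AnnotationSet, db: InteractionDB | None = None
) -> frozenset[str]:
    """Extension of a conjunction: intersection of per-literal gene sets."""
    literals = tuple(literals)
    if not literals:
        raise SegrulesError("a rule needs at least one literal")
    covered = ann.universe
    for lit in literals:
        if lit.term not in ann.propagated:
            raise ValidationError(f"literal references unknown term {lit.term!r}")
        if lit.kind == TERM:
            genes = ann.propagated[lit.term]
        elif lit.kind == INT:
            if db is None:
                raise ValidationError("INT literal requires an interaction database")
            genes = interacting_set(ann.propagated[lit.term], db) & ann.universe
        else:
            raise ValidationError(f"unknown literal kind {lit.kind!r}")
        covered = covered & genes
    return covered


def generate_candidates(
    onto: Ontology,
    ann: AnnotationSet,
    db: InteractionDB | None,
    params: SearchParams,
    stats: SearchStats | None = None,
) -> list[Rule]:
    """Enumerate every rule of the hypothesis language within ``params``.

    Slots are ordered BP, MF, CC, KEGG, INT; output is sorted
    lexicographically by (slot, ontology file position) of the literals, so
    results are deterministic and independent of annotation or interaction
    input ordering.  Terms missing from ``ann`` (e.g. removed by
    :func:`filter_general_terms`) cannot form literals but stay transparent:
    their children are still reachable.
    """
    if stats is None:
        stats = SearchStats()
    branches = [b for b in params.branches_enabled if b in onto.branches]
    slots: list[tuple[str, tuple[str, ...]]] = [(TERM, (b,)) for b in branches]
    if params.allow_int and db is not None:
        slots.append((INT, tuple(branches)))

    allowed = set(ann.propagated)
    topo = {b: onto.topological_order(b) for b in branches}
    file_order = {b: onto.branch_terms(b) for b in branches}
    int_cov: dict[str, frozenset[str]] = {}

    def literal_cov(kind: str, term: str) -> frozenset[str]:
        if kind == TERM:
            return ann.propagated[term]
        if term not in int_cov:
            int_cov[term] = interacting_set(ann.propagated[term], db) & ann.universe
        return int_cov[term]

    # nearest allowed ancestors of a term, walking through filtered terms
    _ancestor_memo: dict[str, frozenset[str]] = {}

    def nearest_allowed_ancestors(t: str) -> frozenset[str]:
        if t not in _ancestor_memo:
            found: set[str] = set()
            for p in onto.parents(t):
                if p in allowed:
                    found.add(p)
                else:
                    found |= nearest_allowed_ancestors(p)
            _ancestor_memo[t] = frozenset(found)
        return _ancestor_memo[t]

    slot_terms: list[list[str]] = [
        [t for branch in slot_branches for t in topo[branch] if t in allowed]
        for _kind, slot_branches in slots
    ]

    # Level-wise (Apriori-style) enumeration: a conjunction is evaluated
    # only after every one-step generalization — drop a literal, or replace
    # a term by its nearest unfiltered ancestor — is known viable.  This
    # guarantees no specialization of a pruned conjunction is ever scored.
    pruned: set[tuple[Literal, ...]] = set()
    all_viable: list[tuple[tuple[Literal, ...], frozenset[str]]] = []

    def classify(combo, prev_cov, lit_cov):
        new_cov = prev_cov & lit_cov
        stats.n_evaluated += 1
        if stats.record:
            stats.evaluated.append(combo)
        if len(new_cov) >= params.min_set_size:
            return new_cov
        _mark_pruned(combo)
        return None

    def _mark_pruned(combo):
        pruned.add(combo)
        stats.n_pruned += 1
        if stats.record:
            stats.pruned.append(combo)

    level: list[tuple[tuple[Literal, ...], frozenset[str], int]] = []
    for j, (kind, _slot_branches) in enumerate(slots):
        for t in slot_terms[j]:
            combo = (Literal(kind, t),)
            gens = [(Literal(kind, p),) for p in nearest_allowed_ancestors(t)]
            if any(g in pruned for g in gens):
                _mark_pruned(combo)
                continue
            cov = classify(combo, ann.universe, literal_cov(kind, t))
            if cov is not None:
                level.append((combo, cov, j))
                all_viable.append((combo, cov))

    for _depth in range(2, params.max_literals + 1):
        next_level: list[tuple[tuple[Literal, ...], frozenset[str], int]] = []
        for combo, cov, last_j in level:
            for j in range(last_j + 1, len(slots)):
                kind, _slot_branches = slots[j]
                for t in slot_terms[j]:
                    lit = Literal(kind, t)
                    new_combo = combo + (lit,)
                    bad = False
                    # same-level generalizations: term -> allowed ancestor
                    for p in nearest_allowed_ancestors(t):
                        if combo + (Literal(kind, p),) in pruned:
                            bad = True
                            break
                    # previous-level generalizations: drop an old literal
                    if not bad:
                        for i in range(len(combo)):
                            dropped = combo[:i] + combo[i + 1 :] + (lit,)
                            if dropped in pruned:
                                bad = True
                                break
                    # same-level generalizations: old term -> ancestor
                    if not bad:
                        for i, old in enumerate(combo):
                            for p in nearest_allowed_ancestors(old.term):
                                repl = (
                                    combo[:i]
                                    + (Literal(old.kind, p),)
                                    + combo[i + 1 :]
                                    + (lit,)
                                )
                                if repl in pruned:
                                    bad = True
                                    break
                            if bad:
                                break
                    if bad:
                        _mark_pruned(new_combo)
                        continue
                    new_cov = classify(new_combo, cov, literal_cov(kind, t))
                    if new_cov is not None:
                        next_level.append((new_combo, new_cov, j))
                        all_viable.append((new_combo, new_cov))
        level = next_level
        if not level:
            break

    # deterministic output order: lexicographic on (slot, file position)
    slot_file_pos: list[dict[str, int]] = [
        {
            t: i
            for i, t in enumerate(
                t for branch in slot_branches for t in file_order[branch]
            )
        }
        for _kind, slot_branches in slots
    ]
    branch_slot = {b: j for j, (kind, bs) in enumerate(slots) if kind == TERM for b in bs}
    int_slot = len(slots) - 1 if params.allow_int and db is not None else None

    def literal_key(lit: Literal) -> tuple[int, int]:
        j = int_slot if lit.kind == INT else branch_slot[onto[lit.term].branch]
        return (j, slot_file_pos[j][lit.term])

    rules = [
        Rule(literals=combo, covered=cov)
        for combo, cov in all_viable
        if params.max_set_size is None or len(cov) <= params.max_set_size
    ]
    rules.sort(key=lambda r: tuple(literal_key(lit) for lit in r.literals))
    stats.n_emitted = len(rules)
    return rules


def count_search_space(onto: Ontology, params: SearchParams) -> int:
    """Size of the literal-combination space, ignoring the coverage filter.

    Product over enabled branch slots of (terms in branch + 1), times
    (1 + number of INT inner-term choices) when INT is enabled, minus the
    all-empty combination.
    """
    branches = [b for b in params.branches_enabled if b in onto.branches]
    total = 1
    n_terms = 0
    for b in branches:
        n_b = len(onto.branch_terms(b))
        total *= n_b + 1
        n_terms += n_b
    if params.allow_int:
        total *= 1 + n_terms
    return total - 1


def is_generalization(rule: Rule, target: Rule, onto: Ontology) -> bool:
    """True when ``rule`` is ``target`` or a generalization of it.

    Every literal of ``rule`` must match a literal of ``target`` of the same
    kind whose term it is an ancestor of (or equal to); ``rule`` may also
    drop literals.  Reflexive: a rule generalizes itself.
    """
    remaining = list(target.literals)
    for lit in rule.literals:
        match = None
        for cand in remaining:
            if cand.kind == lit.kind and lit.term in onto.ancestors(cand.term):
                match = cand
                break
        if match is None:
            return False
        remaining.remove(match)
    return True
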