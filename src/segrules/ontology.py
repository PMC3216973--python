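"""Ontology DAG, gene annotations and gene-gene interactions.

The hypothesis language of the rule search is built from terms of a
multi-branch ontology (the three Gene Ontology branches plus KEGG pathways,
modelled as a flat branch) connected by ``is_a`` and ``part_of`` edges, from
term-to-gene annotations propagated up the hierarchy (true-path rule), and
from an undirected gene-gene interaction database supporting the interaction
closure operator ``INT``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical branch order used everywhere (search slots, output ordering).
BRANCHES = ("BP", "MF", "CC", "KEGG")

_NAMESPACE_TO_BRANCH = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "kegg": "KEGG",
}
_BRANCH_TO_NAMESPACE = {v: k for k, v in _NAMESPACE_TO_BRANCH.items()}

#: Hierarchical relations the search understands; everything else is ignored.
RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class Term:
    """One ontology term.

    parents is a tuple of (parent term id, relation) pairs; relation is
    ``is_a`` or ``part_of``.  Both relations are treated identically for
    annotation propagation and search refinement.
    """

    id: str
    name: str
    branch: str
    parents: tuple[tuple[str, str], ...] = ()


class Ontology:
    """A validated multi-branch DAG of :class:`Term` objects.

    Terms keep file/insertion order, which fixes the deterministic ordering
    of the candidate search.  Validation enforces: unique ids, parents exist,
    no parent edge crosses branches, the parent graph is acyclic, and each
    branch present has exactly one root (parentless term).
    """

    def __init__(self, terms: Iterable[Term]):
        self._terms: dict[str, Term] = {}
        for t in terms:
            if t.id in self._terms:
                raise ValidationError(f"duplicate term id {t.id!r}")
            if t.branch not in BRANCHES:
                raise ValidationError(f"term {t.id!r}: unknown branch {t.branch!r}")
            self._terms[t.id] = t
        self._children: dict[str, list[str]] = {tid: [] for tid in self._terms}
        for t in self._terms.values():
            for pid, rel in t.parents:
                if pid not in self._terms:
                    raise ValidationError(f"term {t.id!r}: unknown parent {pid!r}")
                if rel not in RELATIONS:
                    raise ValidationError(f"term {t.id!r}: unknown relation {rel!r}")
                if self._terms[pid].branch != t.branch:
                    raise ValidationError(
                        f"parent edge {t.id} -> {pid} crosses branches "
                        f"({t.branch} vs {self._terms[pid].branch})"
                    )
                self._children[pid].append(t.id)
        self._check_acyclic()
        self.roots: dict[str, str] = {}
        for t in self._terms.values():
            if not t.parents:
                if t.branch in self.roots:
                    raise ValidationError(
                        f"branch {t.branch} has multiple roots: "
                        f"{self.roots[t.branch]!r} and {t.id!r}"
                    )
                self.roots[t.branch] = t.id
        for b in self.branches:
            if b not in self.roots:
                raise ValidationError(f"branch {b} has no root")

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._terms)
        for t in self._terms.values():
            for pid, _rel in t.parents:
                g.add_edge(t.id, pid)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(a for a, _b in cycle) + f" -> {cycle[0][0]}"
            raise ValidationError(f"cycle in parent graph: {path}")

    # -- basic access -----------------------------------------------------
    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __getitem__(self, term_id: str) -> Term:
        return self._terms[term_id]

    @property
    def terms(self) -> list[Term]:
        """All terms in file/insertion order."""
        return list(self._terms.values())

    @property
    def branches(self) -> list[str]:
        """Branches present, in canonical BP, MF, CC, KEGG order."""
        present = {t.branch for t in self._terms.values()}
        return [b for b in BRANCHES if b in present]

    def branch_terms(self, branch: str) -> list[str]:
        """Term ids of one branch in file order."""
        return [t.id for t in self._terms.values() if t.branch == branch]

    def parents(self, term_id: str) -> list[str]:
        return [pid for pid, _rel in self._terms[term_id].parents]

    def children(self, term_id: str) -> list[str]:
        return list(self._children[term_id])

    def n_parent_edges(self) -> int:
        return sum(len(t.parents) for t in self._terms.values())

    def descendants(self, term_id: str) -> set[str]:
        """All terms reachable downward from term_id, including itself."""
        seen = {term_id}
        stack = [term_id]
        while stack:
            for c in self._children[stack.pop()]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return seen

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable upward from term_id, including itself."""
        seen = {term_id}
        stack = [term_id]
        while stack:
            for p in self.parents(stack.pop()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    def topological_order(self, branch: str) -> list[str]:
        """Branch term ids with every parent before its children.

        Stable with respect to file order: among terms whose parents are all
        placed, the one earliest in the file comes first.
        """
        ids = self.branch_terms(branch)
        pos = {tid: i for i, tid in enumerate(ids)}
        remaining_parents = {tid: len(self._terms[tid].parents) for tid in ids}
        ready = sorted((tid for tid in ids if remaining_parents[tid] == 0), key=pos.get)
        order: list[str] = []
        import heapq

        heap = [pos[tid] for tid in ready]
        heapq.heapify(heap)
        while heap:
            tid = ids[heapq.heappop(heap)]
            order.append(tid)
            for c in self._children[tid]:
                remaining_parents[c] -= 1
                if remaining_parents[c] == 0:
                    heapq.heappush(heap, pos[c])
        return order


# -- OBO-lite parsing ------------------------------------------------------

def load_obo_lite(path) -> Ontology:
    """Parse an OBO-lite file into an :class:`Ontology`.

    Recognized stanza keys: ``id:``, ``name:``, ``namespace:``, ``is_a:``,
    ``relationship: part_of <id>``, ``is_obsolete: true``.  Obsolete terms
    are skipped; unrecognized keys and non-``[Term]`` stanzas are ignored.
    Trailing ``! comment`` text on id references is stripped.
    """
    terms: list[Term] = []
    stanza: dict | None = None
    stanza_line = 0

    def close(stanza: dict, line: int) -> None:
        if stanza.get("obsolete"):
            return
        if "id" not in stanza:
            raise ParseError("[Term] stanza without id:", line=line)
        if "branch" not in stanza:
            raise ParseError(
                f"term {stanza['id']!r}: missing or unrecognized namespace:",
                line=line,
            )
        terms.append(
            Term(
                id=stanza["id"],
                name=stanza.get("name", ""),
                branch=stanza["branch"],
                parents=tuple(stanza.get("parents", ())),
            )
        )

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("["):
                if stanza is not None:
                    close(stanza, stanza_line)
                stanza = {} if line == "[Term]" else None
                stanza_line = lineno
                continue
            if stanza is None or not line or line.startswith("!"):
                continue
            if ":" not in line:
                raise ParseError(f"malformed line {line!r}", line=lineno)
            key, _, value = line.partition(":")
            key = key.strip()
            value = value.split("!")[0].strip()
            if key == "id":
                if not value:
                    raise ParseError("empty id:", line=lineno)
                stanza["id"] = value
            elif key == "name":
                stanza["name"] = value
            elif key == "namespace":
                if value not in _NAMESPACE_TO_BRANCH:
                    raise ParseError(f"unrecognized namespace {value!r}", line=lineno)
                stanza["branch"] = _NAMESPACE_TO_BRANCH[value]
            elif key == "is_a":
                if not value:
                    raise ParseError("is_a without a target id", line=lineno)
                stanza.setdefault("parents", []).append((value, "is_a"))
            elif key == "relationship":
                parts = value.split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    stanza.setdefault("parents", []).append((parts[1], "part_of"))
                # other relationship types ignored
            elif key == "is_obsolete" and value.lower() == "true":
                stanza["obsolete"] = True
    if stanza is not None:
        close(stanza, stanza_line)
    return Ontology(terms)


def write_obo_lite(onto: Ontology, path) -> None:
    """Write an ontology back out in the OBO-lite dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for t in onto.terms:
            fh.write("\n[Term]\n")
            fh.write(f"id: {t.id}\n")
            fh.write(f"name: {t.name}\n")
            fh.write(f"namespace: {_BRANCH_TO_NAMESPACE[t.branch]}\n")
            for pid, rel in t.parents:
                if rel == "is_a":
                    fh.write(f"is_a: {pid}\n")
                else:
                    fh.write(f"relationship: part_of {pid}\n")


# -- annotations -----------------------------------------------------------

@dataclass
class AnnotationSet:
    """Direct and hierarchy-propagated term-to-gene annotations.

    ``propagated[t]`` is the union of direct annotations over all
    descendants of ``t`` (true-path rule); ``universe`` is the set of all
    annotated genes and serves as the statistical background.
    """

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    universe: frozenset[str]

    def terms(self) -> list[str]:
        return list(self.propagated)

    def restrict(self, genes: Iterable[str]) -> "AnnotationSet":
        """Intersect every term set and the universe with ``genes``.

        Used to align the annotation background with the measured/ranked
        gene universe before enrichment scoring.
        """
        keep = frozenset(genes)
        return AnnotationSet(
            direct={t: s & keep for t, s in self.direct.items()},
            propagated={t: s & keep for t, s in self.propagated.items()},
            universe=self.universe & keep,
        )


def propagate_annotations(
    onto: Ontology, direct: Mapping[str, Iterable[str]]
) -> AnnotationSet:
    """True-path closure of direct annotations over is_a/part_of edges.

    Every ontology term gets a propagated entry (possibly empty); the gene
    universe is the union of all direct annotations.
    """
    unknown = sorted(t for t in direct if t not in onto)
    if unknown:
        raise ValidationError(f"annotations reference unknown terms: {unknown}")
    direct_fz = {t: frozenset(gs) for t, gs in direct.items()}
    propagated: dict[str, frozenset[str]] = {}
    for branch in onto.branches:
        # children before parents
        for tid in reversed(onto.topological_order(branch)):
            acc = set(direct_fz.get(tid, ()))
            for c in onto.children(tid):
                acc |= propagated[c]
            propagated[tid] = frozenset(acc)
    universe = frozenset().union(*direct_fz.values()) if direct_fz else frozenset()
    return AnnotationSet(direct=direct_fz, propagated=propagated, universe=universe)


def filter_general_terms(
    ann: AnnotationSet,
    blocklist: Iterable[str] = (),
    max_genes: int | None = None,
) -> AnnotationSet:
    """Drop overly general terms from the hypothesis language.

    Terms on the blocklist, and terms whose propagated gene set exceeds
    ``max_genes`` (when given), are removed from the annotation maps; the
    gene universe — the statistical background — is unchanged.  Unknown
    blocklist ids are ignored with a warning.
    """
    blockset = set(blocklist)
    unknown = blockset - set(ann.propagated)
    if unknown:
        logger.warning("blocklist ids not in annotations ignored: %s", sorted(unknown))
    removed = {
        t
        for t, genes in ann.propagated.items()
        if t in blockset or (max_genes is not None and len(genes) > max_genes)
    }
    return AnnotationSet(
        direct={t: s for t, s in ann.direct.items() if t not in removed},
        propagated={t: s for t, s in ann.propagated.items() if t not in removed},
        universe=ann.universe,
    )


# -- GMT I/O ---------------------------------------------------------------

def load_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: set id, description, then gene ids, tab-separated."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("GMT line needs at least id and description", line=lineno)
            out[parts[0]] = {g for g in parts[2:] if g}
    return out


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for sid, genes in sets.items():
            desc = descriptions.get(sid, "")
            fh.write("\t".join([sid, desc, *sorted(genes)]) + "\n")


# -- interactions ----------------------------------------------------------

class InteractionDB:
    """Undirected gene-gene interaction pairs with an adjacency index."""

    def __init__(
        self,
        pairs: Iterable[tuple[str, str]],
        universe: Iterable[str] | None = None,
        strict: bool = False,
    ):
        self.pairs: frozenset[tuple[str, str]] = frozenset(
            (a, b) if a <= b else (b, a) for a, b in pairs
        )
        if strict and universe is not None:
            uni = set(universe)
            bad = sorted({g for p in self.pairs for g in p if g not in uni})
            if bad:
                raise ValidationError(f"interaction genes outside universe: {bad}")
        self._neighbors: dict[str, set[str]] = {}
        for a, b in self.pairs:
            self._neighbors.setdefault(a, set()).add(b)
            self._neighbors.setdefault(b, set()).add(a)

    def __len__(self) -> int:
        return len(self.pairs)

    def neighbors(self, gene: str) -> frozenset[str]:
        return frozenset(self._neighbors.get(gene, ()))

    @classmethod
    def from_tsv(cls, path, universe=None, strict=False) -> "InteractionDB":
        """Two-column TSV; duplicates and reversed duplicates collapse."""
        pairs = []
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError("interaction line needs two columns", line=lineno)
                pairs.append((parts[0], parts[1]))
        return cls(pairs, universe=universe, strict=strict)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in sorted(self.pairs):
                fh.write(f"{a}\t{b}\n")


def interacting_set(genes: Iterable[str], db: InteractionDB) -> frozenset[str]:
    """Interaction closure INT(S): genes with a recorded interaction partner in S.

    A member of S is included only if some interaction pair witnesses it;
    self-pairs count only when explicitly listed.
    """
    out: set[str] = set()
    for g in genes:
        out |= db._neighbors.get(g, set())
    return frozenset(out)
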