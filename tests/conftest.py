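"""Shared fixtures: hand-built ontologies and small synthetic studies."""

from __future__ import annotations

import numpy as np
import pytest

from segrules.ontology import (
    AnnotationSet,
    InteractionDB,
    Ontology,
    Term,
    propagate_annotations,
)
from segrules.preprocess import ExpressionDataset, RankedGene, RankedGeneList


def make_chain_ontology():
    """root <- A <- B in one branch."""
    return Ontology(
        [
            Term("BP:root", "root", "BP"),
            Term("BP:A", "a", "BP", (("BP:root", "is_a"),)),
            Term("BP:B", "b", "BP", (("BP:A", "is_a"),)),
        ]
    )


def random_dag_ontology(rng: np.random.Generator, branch="BP", n_terms=20):
    """Random single-branch DAG: term i gets 1-2 parents among terms < i."""
    terms = [Term(f"{branch}:0", f"{branch.lower()} 0", branch)]
    for i in range(1, n_terms):
        n_par = 1 if i == 1 else int(rng.integers(1, 3))
        parents = rng.choice(i, size=min(n_par, i), replace=False)
        rels = tuple(
            (f"{branch}:{p}", "is_a" if rng.random() < 0.7 else "part_of")
            for p in sorted(parents)
        )
        terms.append(Term(f"{branch}:{i}", f"{branch.lower()} {i}", branch, rels))
    return Ontology(terms)


def random_annotations(rng, onto: Ontology, genes, rate=0.2):
    direct = {}
    for t in onto.terms:
        mask = rng.random(len(genes)) < rate
        picked = {g for g, m in zip(genes, mask) if m}
        if picked:
            direct[t.id] = picked
    return propagate_annotations(onto, direct)


def ranked_from_scores(pairs, method="precomputed"):
    """Build a RankedGeneList from (gene, score, logfc) tuples, sorting."""
    entries = sorted(
        (RankedGene(g, float(s), float(l)) for g, s, l in pairs),
        key=lambda e: -e.score,
    )
    return RankedGeneList(entries, method=method)


@pytest.fixture
def chain_ontology():
    return make_chain_ontology()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset():
    """3 genes x 4 samples, two balanced classes."""
    return ExpressionDataset(
        genes=["g1", "g2", "g3"],
        samples=["s1", "s2", "s3", "s4"],
        values=np.array([[2.0, 4.0, 1.0, 1.0], [5.0, 5.0, 5.0, 5.0], [0.0, 1.0, 2.0, 3.0]]),
        labels={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        class_order=("A", "B"),
    )
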