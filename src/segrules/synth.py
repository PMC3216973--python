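"""Synthetic ontologies, annotations, interactions and expression data.

The generator emulates the statistical structure the rule search assumes: a
multi-branch ontology (rooted trees with occasional extra DAG edges), genes
directly annotated to random leaves with true-path propagation, a uniform
random interaction network, and a two-class log2-scale expression matrix in
which the genes covered by an optional planted conjunctive rule are shifted
upward in class A by a fixed effect size.  Everything is bit-reproducible
from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import SegrulesError, ValidationError
from .ontology import (
    BRANCHES,
    AnnotationSet,
    InteractionDB,
    Ontology,
    Term,
    propagate_annotations,
    write_gmt,
    write_obo_lite,
)
from .preprocess import ExpressionDataset
from .search import TERM, Literal, evaluate_rule


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a small two-class microarray study: 500 genes, four
    ontology branches of 15 terms (ternary trees), sparse leaf annotation,
    300 random interactions, 6 samples per class, within-class noise of
    0.5 on the log2 scale and a planted shift of 1.5 (3x the noise) on the
    genes covered by the planted rule, if any.
    """

    n_genes: int = 500
    terms_per_branch: int = 15
    branching_factor: int = 3
    annotation_rate: float = 0.05
    n_interactions: int = 300
    planted_rule: tuple[Literal, ...] | None = None
    planted_set_size: int = 20
    effect_size: float = 1.5
    noise_sd: float = 0.5
    n_samples_per_class: int = 6
    seed: int = 0
    branches: tuple[str, ...] = BRANCHES
    extra_parent_rate: float = 0.1

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        for name in ("n_genes", "terms_per_branch", "branching_factor",
                     "n_samples_per_class"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        bad = set(self.branches) - set(BRANCHES)
        if bad:
            raise ValidationError(f"unknown branches: {sorted(bad)}")


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stream,))
    )


def _gene_ids(cfg: SynthConfig) -> list[str]:
    width = len(str(cfg.n_genes - 1))
    return [f"G{i:0{width}d}" for i in range(cfg.n_genes)]


def make_ontology(cfg: SynthConfig) -> tuple[Ontology, AnnotationSet]:
    """Build the branch trees and leaf annotations, then propagate.

    Each branch is a rooted ``branching_factor``-ary tree of
    ``terms_per_branch`` terms; with probability ``extra_parent_rate`` a
    non-root term gains a second ``part_of`` parent, turning the tree into a
    proper DAG.  Every gene is directly annotated to each leaf independently
    with probability ``annotation_rate``.  A planted rule's TERM literals
    additionally receive ``planted_set_size`` shared genes so the planted
    conjunction has a guaranteed extension.
    """
    rng = _rng(cfg, 0)
    terms: list[Term] = []
    leaves: dict[str, list[str]] = {}
    for branch in cfg.branches:
        ids = [f"{branch}:{i:04d}" for i in range(cfg.terms_per_branch)]
        children_count = {tid: 0 for tid in ids}
        for i, tid in enumerate(ids):
            parents: tuple[tuple[str, str], ...] = ()
            if i > 0:
                primary = ids[(i - 1) // cfg.branching_factor]
                parents = ((primary, "is_a"),)
                children_count[primary] += 1
                if i > 1 and rng.random() < cfg.extra_parent_rate:
                    others = [t for t in ids[:i] if t != primary]
                    extra = others[int(rng.integers(len(others)))]
                    parents = parents + ((extra, "part_of"),)
                    children_count[extra] += 1
            terms.append(
                Term(
                    id=tid,
                    name=f"synthetic {branch.lower()} term {i}",
                    branch=branch,
                    parents=parents,
                )
            )
        leaves[branch] = [tid for tid in ids if children_count[tid] == 0]
    onto = Ontology(terms)

    genes = _gene_ids(cfg)
    direct: dict[str, set[str]] = {}
    for branch in cfg.branches:
        for leaf in leaves[branch]:
            mask = rng.random(cfg.n_genes) < cfg.annotation_rate
            annotated = {genes[i] for i in np.nonzero(mask)[0]}
            if annotated:
                direct[leaf] = annotated
    if cfg.planted_rule:
        planted_terms = [lit.term for lit in cfg.planted_rule if lit.kind == TERM]
        unknown = [t for t in planted_terms if t not in onto]
        if unknown:
            raise ValidationError(f"planted rule references unknown terms: {unknown}")
        chosen = rng.choice(cfg.n_genes, size=cfg.planted_set_size, replace=False)
        planted_genes = {genes[i] for i in chosen}
        for t in planted_terms:
            direct.setdefault(t, set()).update(planted_genes)
    return onto, propagate_annotations(onto, direct)


def make_interactions(cfg: SynthConfig, universe) -> InteractionDB:
    """Draw ``n_interactions`` distinct unordered pairs uniformly."""
    uni = sorted(universe)
    m = len(uni)
    total = m * (m - 1) // 2
    if cfg.n_interactions > total:
        raise ValidationError(
            f"n_interactions={cfg.n_interactions} exceeds C({m},2)={total}"
        )
    if cfg.n_interactions == 0:
        return InteractionDB([])
    rng = _rng(cfg, 1)
    iu, ju = np.triu_indices(m, k=1)
    picks = rng.choice(total, size=cfg.n_interactions, replace=False)
    return InteractionDB((uni[iu[k]], uni[ju[k]]) for k in picks)


def make_expression(
    cfg: SynthConfig,
    onto: Ontology,
    ann: AnnotationSet,
    db: InteractionDB | None = None,
) -> tuple[ExpressionDataset, frozenset[str]]:
    """Two-class log2-scale matrix with the planted shift applied to class A.

    Per-gene baselines are uniform on [6, 10]; all cells get i.i.d. normal
    noise with sd ``noise_sd``; genes covered by the planted rule gain
    ``effect_size`` in class A only.  Returns the dataset and the true
    covered gene set (empty when no rule is planted).
    """
    rng = _rng(cfg, 2)
    covered: frozenset[str] = frozenset()
    if cfg.planted_rule:
        covered = evaluate_rule(cfg.planted_rule, ann, db)
        if not covered:
            raise SegrulesError("planted rule covers no genes")
    genes = _gene_ids(cfg)
    s = cfg.n_samples_per_class
    baseline = rng.uniform(6.0, 10.0, size=cfg.n_genes)
    values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, 2 * s))
    idx = [i for i, g in enumerate(genes) if g in covered]
    values[np.ix_(idx, range(s))] += cfg.effect_size
    samples = [f"A{i + 1}" for i in range(s)] + [f"B{i + 1}" for i in range(s)]
    labels = {smp: smp[0] for smp in samples}
    ds = ExpressionDataset(
        genes=genes,
        samples=samples,
        values=values,
        labels=labels,
        class_order=("A", "B"),
    )
    return ds, covered


@dataclass
class SynthStudy:
    """One fully generated synthetic study."""

    config: SynthConfig
    ontology: Ontology
    annotations: AnnotationSet
    interactions: InteractionDB
    dataset: ExpressionDataset
    planted_covered: frozenset[str]


def make_study(cfg: SynthConfig) -> SynthStudy:
    onto, ann = make_ontology(cfg)
    db = make_interactions(cfg, ann.universe)
    ds, covered = make_expression(cfg, onto, ann, db)
    return SynthStudy(cfg, onto, ann, db, ds, covered)


def leaf_terms(onto: Ontology, branch: str) -> list[str]:
    """Branch terms without children, in file order."""
    return [t for t in onto.branch_terms(branch) if not onto.children(t)]


def default_planted_rule(cfg: SynthConfig) -> tuple[Literal, ...]:
    """A canonical two-literal planted rule: the last leaf of each of the
    first two branches (deterministic for a given config shape)."""
    onto, _ = make_ontology(replace(cfg, planted_rule=None))
    b1, b2 = cfg.branches[0], cfg.branches[1]
    return (
        Literal(TERM, leaf_terms(onto, b1)[-1]),
        Literal(TERM, leaf_terms(onto, b2)[-1]),
    )


def write_study(study: SynthStudy, outdir) -> None:
    """Write expr.tsv, labels.tsv, onto.obo, ann.gmt, interactions.tsv,
    truth.json for use by the file-based CLI pipeline."""
    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds = study.dataset
    pd.DataFrame(ds.values, index=pd.Index(ds.genes, name="gene"), columns=ds.samples).to_csv(
        out / "expr.tsv", sep="\t", float_format="%.10g"
    )
    pd.DataFrame(
        {"sample": ds.samples, "class": [ds.labels[s] for s in ds.samples]}
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
    write_obo_lite(study.ontology, out / "onto.obo")
    write_gmt(study.annotations.direct, out / "ann.gmt")
    study.interactions.to_tsv(out / "interactions.tsv")
    truth = {
        "planted_rule": [
            {"kind": lit.kind, "term": lit.term} for lit in (study.config.planted_rule or ())
        ],
        "covered_genes": sorted(study.planted_covered),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
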