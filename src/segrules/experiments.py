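"""Calibration experiments run on synthetic studies.

Two standard checks of the whole pipeline:

* type-I error — on null data (no planted effect) the family-wise
  permutation correction should report any significant rule in about an
  alpha fraction of independent studies;
* planted-rule recovery — with a strong planted conjunctive signal the
  top-ranked rule should be the planted rule or a generalization of it
  (an ancestor term or a dropped literal) in nearly all replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .enrichment import EnrichmentConfig
from .pipeline import analyze
from .preprocess import rank_ttest
from .search import Rule, SearchParams, is_generalization
from .synth import SynthConfig, default_planted_rule, make_study

#: Null study conditions: two ontology branches of 7 terms, 120 genes,
#: no planted effect.  Small enough to replicate a few hundred times.
NULL_SYNTH = SynthConfig(
    n_genes=120,
    terms_per_branch=7,
    branching_factor=3,
    annotation_rate=0.15,
    n_interactions=150,
    planted_rule=None,
    effect_size=0.0,
    noise_sd=0.5,
    n_samples_per_class=6,
    branches=("BP", "MF"),
)

NULL_SEARCH = SearchParams(min_set_size=5, max_literals=2, branches_enabled=("BP", "MF"))

NULL_ENRICH = EnrichmentConfig(
    top_k=30, gsea_permutations=100, correction="permutation", n_permutations=99
)

#: Recovery study conditions: 500 genes, four 15-term branches, a planted
#: two-literal rule covering ~20 genes with a 3x-noise expression shift.
RECOVERY_SYNTH = SynthConfig(
    n_genes=500,
    terms_per_branch=15,
    branching_factor=3,
    annotation_rate=0.05,
    n_interactions=300,
    planted_set_size=20,
    effect_size=1.5,
    noise_sd=0.5,
    n_samples_per_class=6,
)

RECOVERY_SEARCH = SearchParams(min_set_size=5, max_literals=2)

RECOVERY_ENRICH = EnrichmentConfig(
    top_k=50, gsea_permutations=100, correction="permutation", n_permutations=99
)


def run_study(cfg: SynthConfig, search: SearchParams, enrich: EnrichmentConfig):
    """Generate one synthetic study and run ranking + search + correction."""
    study = make_study(cfg)
    ranked = rank_ttest(study.dataset)
    result = analyze(
        ranked, study.ontology, study.annotations, study.interactions, search, enrich
    )
    return study, result


def type_i_error_rate(
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    synth: SynthConfig = NULL_SYNTH,
    search: SearchParams = NULL_SEARCH,
    enrich: EnrichmentConfig = NULL_ENRICH,
) -> float:
    """Fraction of null studies reporting any rule with corrected p <= alpha."""
    hits = 0
    for r in range(n_replicates):
        s = (seed * 100003 + r) % (2**31)
        study, result = run_study(
            replace(synth, seed=s), search, replace(enrich, seed=s, alpha=alpha)
        )
        if result.significant(alpha):
            hits += 1
    return hits / n_replicates


def recovery_rate(
    n_replicates: int,
    seed: int,
    synth: SynthConfig = RECOVERY_SYNTH,
    search: SearchParams = RECOVERY_SEARCH,
    enrich: EnrichmentConfig = RECOVERY_ENRICH,
) -> float:
    """Fraction of replicates whose best corrected rule is the planted rule
    or a generalization of it."""
    planted = default_planted_rule(synth)
    hits = 0
    for r in range(n_replicates):
        s = (seed * 100003 + r) % (2**31)
        cfg = replace(synth, seed=s, planted_rule=planted)
        study, result = run_study(cfg, search, replace(enrich, seed=s))
        if not result.rules:
            continue
        top = result.rules[0]
        target = Rule(literals=planted, covered=study.planted_covered)
        if is_generalization(top, target, study.ontology):
            hits += 1
    return hits / n_replicates
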