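# segrules

Semantic gene-set enrichment for two-class expression studies: instead of
testing a fixed catalogue of gene sets, `segrules` searches a hypothesis
language of **conjunctive rules** built from ontology terms — the three Gene
Ontology branches (BP, MF, CC) plus KEGG pathways — and an interaction
operator, and reports the conjunctions whose gene sets are differentially
expressed. A rule such as

```
lymphocyte differentiation ∧ interacting with phagocytosis
```

covers the genes annotated (directly or via the true-path rule) to the first
term **and** having a recorded interaction with a gene annotated to the
second. Rules are more specific than single terms, which makes them better
raw material for hypothesis generation; a built-in clustering step then
groups near-duplicate rules, and an overlap matrix compares rule gene sets
with any reference collection (e.g. another tool's output).

It is aimed at transcriptomics practitioners analysing microarray or
bulk/pseudobulk RNA expression with two sample classes, who want readable,
ontology-level descriptions of what separates the classes.

## Method

1. **Preprocess** — load a genes × samples log2 matrix with class labels,
   resolve gene synonyms, compute logFC(g) = mean_A(g) − mean_B(g), rank
   genes by Welch's t or ReliefF, drop genes with |logFC| below a cutoff,
   optionally split into up-/down-regulated lists.
2. **Search** — enumerate every conjunction of at most one term per branch
   plus at most one interaction literal INT(t) = {g : ∃g′ ∈ genes(t),
   (g, g′) interacts}. The extension of a conjunction is the intersection of
   its literals' propagated gene sets. Enumeration is top-down and
   level-wise with anti-monotone pruning: once a conjunction covers fewer
   than `min_set_size` genes, none of its specializations (child terms,
   extra literals) is ever evaluated.
3. **Score** — each rule's gene set is tested with Fisher's exact test
   (over-representation in the top-k ranked genes vs the remainder), classic
   GSEA (running-sum enrichment score with an empirical permutation p), and
   PAGE (z = (S̄ₘ − μ)·√m/δ against the global logFC distribution). The
   three p-values combine into a weighted mean p = Σwᵢpᵢ/Σwᵢ (equal weights
   by default) — a ranking heuristic, not a calibrated probability — and
   family-wise significance comes from permutation testing (maxT over the
   per-permutation minimum aggregate p), or Bonferroni/BH-FDR.
4. **Summarize** — significant rules are encoded as binary membership
   vectors and clustered agglomeratively (Ward/complete/single/average on
   Euclidean/Manhattan/Hamming/Jaccard distances); rule-vs-reference
   coverage is v(i,j) = |Sᵢ ∩ Dⱼ| / |Dⱼ|.

## Worked example

The synthetic-data module generates a full study — ontology, annotations,
interaction network, and a two-class expression matrix with a planted
conjunctive signal — so the whole pipeline runs without downloads:

```python
from dataclasses import replace
from segrules.synth import SynthConfig, default_planted_rule, make_study
from segrules.preprocess import rank_ttest
from segrules.pipeline import analyze
from segrules.search import SearchParams
from segrules.enrichment import EnrichmentConfig

base = SynthConfig(n_genes=300, terms_per_branch=7, annotation_rate=0.08,
                   n_interactions=200, planted_set_size=15, effect_size=1.5,
                   noise_sd=0.5, branches=("BP", "MF"), seed=42)
cfg = replace(base, planted_rule=default_planted_rule(base))
study = make_study(cfg)

ranked = rank_ttest(study.dataset)
result = analyze(ranked, study.ontology, study.annotations, study.interactions,
                 SearchParams(min_set_size=5, max_literals=2,
                              branches_enabled=("BP", "MF")),
                 EnrichmentConfig(top_k=40, gsea_permutations=100,
                                  n_permutations=99, seed=42))
```

Output (abridged):

```
232 rules scored, 30 significant at alpha=0.05
synthetic bp term 6 ∧ synthetic mf term 6 | genes=19 p_fisher=2.46e-19 p_gsea=0.0099 p_page=1.1e-40  p_agg=0.0033 p_corr=0.01
synthetic bp term 6 ∧ synthetic mf term 1 | genes=22 p_fisher=3.03e-16 p_gsea=0.0099 p_page=3.84e-35 p_agg=0.0033 p_corr=0.01
synthetic bp term 1 ∧ synthetic mf term 6 | genes=23 p_fisher=1.62e-15 p_gsea=0.0099 p_page=5.14e-33 p_agg=0.0033 p_corr=0.01
```

The top rule is exactly the planted conjunction (19 genes); the next two
replace one of its terms by a parent term, covering slight supersets with
slightly weaker evidence. `p_corr = 0.01` is the smallest value 99
permutations can certify ( (0+1)/(99+1) ).

The same flow is available from the shell:

```bash
segrules synth --config synth.yaml -o data/
segrules preprocess --expr data/expr.tsv --labels data/labels.tsv -o ranked.tsv
segrules search --ranked ranked.tsv --obo data/onto.obo --gmt data/ann.gmt \
    --interactions data/interactions.tsv --min-set-size 5 --max-literals 2 \
    --top-k 40 -o rules.json
segrules cluster --rules rules.json --linkage ward -k 9 -o clusters.json
segrules compare --rules rules.json --reference ref.gmt -o overlap.tsv
segrules run --config pipeline.yaml      # everything from one YAML
```

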