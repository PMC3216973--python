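"""End-to-end workflow: preprocess -> rule search + enrichment -> clustering.

`analyze` is the in-memory core used by tests and experiments;
`run_pipeline` adds file I/O around it (load inputs per a YAML-serializable
config, write ranked.tsv, rules.json, clusters.json and the rule report).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple

import yaml

from .cluster import Dendrogram, cluster_rules, cut_clusters, rule_distances
from .enrichment import (
    EnrichmentConfig,
    EnrichmentResult,
    correct_bonferroni,
    correct_fdr,
    correct_permutation,
    score_rules,
)
from .errors import SegrulesError, ValidationError
from .ontology import (
    AnnotationSet,
    InteractionDB,
    Ontology,
    filter_general_terms,
    load_gmt,
    load_obo_lite,
    propagate_annotations,
)
from .preprocess import (
    ExpressionDataset,
    RankedGeneList,
    filter_by_logfc,
    load_expression,
    load_synonyms,
    rank_relieff,
    rank_ttest,
    resolve_synonyms,
)
from .search import Rule, SearchParams, SearchStats, generate_candidates

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Aggregated configuration of the full workflow (YAML-mirrorable)."""

    # inputs
    expr: str = ""
    labels: str = ""
    obo: str = ""
    gmt: str = ""
    interactions: str | None = None
    synonyms: str | None = None
    blocklist: str | None = None
    reference: str | None = None
    # preprocess
    rank_method: str = "ttest"
    k_neighbors: int = 5
    relieff_iterations: int | None = None
    logfc_cutoff: float = 0.0
    class_order: tuple[str, str] | None = None
    missing_policy: str = "drop_gene"
    replicate_policy: str = "mean"
    max_term_genes: int | None = None
    # search
    search: SearchParams = field(default_factory=SearchParams)
    # enrichment
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    # clustering
    metric: str = "euclidean"
    linkage: str = "ward"
    n_clusters: int = 9
    # output
    outdir: str = "segrules_out"
    report_format: str = "tsv"
    top_rules: int | None = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        search = SearchParams(**raw.pop("search", {}))
        enrichment = EnrichmentConfig(**raw.pop("enrichment", {}))
        if "class_order" in raw and raw["class_order"] is not None:
            raw["class_order"] = tuple(raw["class_order"])
        return cls(search=search, enrichment=enrichment, **raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


class ReportRow(NamedTuple):
    rule_id: str
    description: str
    n_genes: int
    genes: tuple[str, ...]
    p_fisher: float | None
    p_gsea: float | None
    p_page: float | None
    p_aggregate: float | None
    p_corrected: float | None
    cluster: int | None


@dataclass
class RuleReport:
    rows: list[ReportRow]


def rank_genes(ds: ExpressionDataset, cfg: PipelineConfig) -> RankedGeneList:
    if cfg.rank_method == "ttest":
        return rank_ttest(ds)
    if cfg.rank_method == "relieff":
        return rank_relieff(
            ds,
            k_neighbors=cfg.k_neighbors,
            n_iterations=cfg.relieff_iterations,
            seed=cfg.enrichment.seed,
        )
    raise ValidationError(f"unknown rank_method {cfg.rank_method!r}")


def analyze(
    ranked: RankedGeneList,
    onto: Ontology,
    ann: AnnotationSet,
    db: InteractionDB | None,
    search_params: SearchParams,
    enrich_cfg: EnrichmentConfig,
    stats: SearchStats | None = None,
) -> EnrichmentResult:
    """Search + score + correct on an already-ranked gene list.

    The annotation universe is first restricted to the ranked genes so the
    statistical background equals the measured universe.
    """
    ann = ann.restrict(ranked.genes)
    rules = generate_candidates(onto, ann, db, search_params, stats=stats)
    if not rules:
        return EnrichmentResult(rules=[], null_best_p=[])
    score_rules(rules, ranked, enrich_cfg)
    if enrich_cfg.correction == "permutation":
        return correct_permutation(rules, ranked, enrich_cfg)
    if enrich_cfg.correction == "bonferroni":
        return correct_bonferroni(rules)
    return correct_fdr(rules)


def build_report(
    result: EnrichmentResult,
    names: dict[str, str],
    labels: dict | None = None,
    alpha: float | None = None,
    top: int | None = None,
) -> RuleReport:
    rows = []
    selected = [
        (i, r)
        for i, r in enumerate(result.rules)
        if alpha is None or (r.p_corrected is not None and r.p_corrected <= alpha)
    ]
    if top is not None:
        selected = selected[:top]
    for row_num, (orig_idx, rule) in enumerate(selected, start=1):
        rows.append(
            ReportRow(
                rule_id=f"R{row_num}",
                description=rule.describe(names),
                n_genes=rule.n_genes,
                genes=tuple(sorted(rule.covered)),
                p_fisher=rule.p_fisher,
                p_gsea=rule.p_gsea,
                p_page=rule.p_page,
                p_aggregate=rule.p_aggregate,
                p_corrected=rule.p_corrected,
                cluster=None if labels is None else labels.get(orig_idx),
            )
        )
    return RuleReport(rows=rows)


_REPORT_COLUMNS = (
    "rule_id description n_genes p_fisher p_gsea p_page p_aggregate "
    "p_corrected cluster".split()
)


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return f"{x:.12g}"
    return str(x)


def write_report(report: RuleReport, path, fmt: str = "tsv") -> None:
    """Write the rule table as TSV or a minimal HTML rendering of it."""
    if not report.rows:
        raise SegrulesError("report is empty")
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_REPORT_COLUMNS) + "\n")
            for row in report.rows:
                fh.write(
                    "\t".join(_fmt(getattr(row, c)) for c in _REPORT_COLUMNS) + "\n"
                )
    elif fmt == "html":
        import html

        with open(path, "w", encoding="utf-8") as fh:
            fh.write("<html><body><table border='1'>\n<tr>")
            fh.write("".join(f"<th>{c}</th>" for c in _REPORT_COLUMNS))
            fh.write("</tr>\n")
            for row in report.rows:
                fh.write(
                    "<tr>"
                    + "".join(
                        f"<td>{html.escape(_fmt(getattr(row, c)))}</td>"
                        for c in _REPORT_COLUMNS
                    )
                    + "</tr>\n"
                )
            fh.write("</table></body></html>\n")
    else:
        raise ValidationError(f"unknown report format {fmt!r}")


def read_report_tsv(path) -> RuleReport:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    rows = []
    for rec in df.itertuples():
        rows.append(
            ReportRow(
                rule_id=str(rec.rule_id),
                description=str(rec.description),
                n_genes=int(rec.n_genes),
                genes=(),
                p_fisher=_opt_float(rec.p_fisher),
                p_gsea=_opt_float(rec.p_gsea),
                p_page=_opt_float(rec.p_page),
                p_aggregate=_opt_float(rec.p_aggregate),
                p_corrected=_opt_float(rec.p_corrected),
                cluster=None if _isnan(rec.cluster) else int(rec.cluster),
            )
        )
    return RuleReport(rows=rows)


def _isnan(x) -> bool:
    try:
        return x != x
    except Exception:
        return False


def _opt_float(x):
    return None if _isnan(x) else float(x)


def rules_to_json(rules: list[Rule], names: dict[str, str]) -> str:
    payload = [
        {
            "literals": [
                {"kind": lit.kind, "term": lit.term, "name": names.get(lit.term, "")}
                for lit in r.literals
            ],
            "genes": sorted(r.covered),
            "p": {
                "fisher": r.p_fisher,
                "gsea": r.p_gsea,
                "page": r.p_page,
                "aggregate": r.p_aggregate,
                "corrected": r.p_corrected,
            },
        }
        for r in rules
    ]
    return json.dumps(payload, indent=1, sort_keys=True)


def _stage(name):
    """Context wrapper: log timing and prefix stage name onto errors."""
    import contextlib

    @contextlib.contextmanager
    def ctx():
        t0 = time.perf_counter()
        try:
            yield
        except Exception as e:
            raise type(e)(f"{name}: {e}") from e
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    return ctx()


def run_pipeline(cfg: PipelineConfig):
    """Execute preprocess -> search+enrichment -> clustering and write artifacts.

    Returns (EnrichmentResult, Dendrogram or None, RuleReport).  The report
    keeps only rules with corrected p <= alpha (capped at ``top_rules``
    rows); the full scored rule set always lands in rules.json.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("preprocess"):
        ds = load_expression(
            cfg.expr,
            cfg.labels,
            missing_policy=cfg.missing_policy,
            replicate_policy=cfg.replicate_policy,
            class_order=cfg.class_order,
        )
        if cfg.synonyms:
            ds = resolve_synonyms(ds, load_synonyms(cfg.synonyms))
        ranked = rank_genes(ds, cfg)
        ranked = filter_by_logfc(ranked, cfg.logfc_cutoff)
        ranked.to_tsv(out / "ranked.tsv")
        logger.info("genes after |logFC| filter: %d", len(ranked))

    with _stage("background"):
        onto = load_obo_lite(cfg.obo)
        ann = propagate_annotations(onto, load_gmt(cfg.gmt))
        blocklist = ()
        if cfg.blocklist:
            blocklist = [
                line.strip()
                for line in Path(cfg.blocklist).read_text().splitlines()
                if line.strip()
            ]
        if blocklist or cfg.max_term_genes is not None:
            ann = filter_general_terms(ann, blocklist, max_genes=cfg.max_term_genes)
        db = InteractionDB.from_tsv(cfg.interactions) if cfg.interactions else None

    with _stage("search+enrichment"):
        stats = SearchStats()
        result = analyze(ranked, onto, ann, db, cfg.search, cfg.enrichment, stats=stats)
        logger.info(
            "candidates evaluated=%d pruned=%d emitted=%d significant=%d",
            stats.n_evaluated,
            stats.n_pruned,
            stats.n_emitted,
            len(result.significant(cfg.enrichment.alpha)),
        )
        names = {t.id: t.name for t in onto.terms}
        (out / "rules.json").write_text(rules_to_json(result.rules, names))

    dendro = None
    labels = None
    with _stage("clustering"):
        significant = result.significant(cfg.enrichment.alpha)
        if len(significant) >= 2:
            dm = rule_distances(
                significant, {g for r in significant for g in r.covered}, cfg.metric
            )
            dendro = cluster_rules(dm, cfg.linkage)
            k = min(cfg.n_clusters, len(significant))
            sig_labels = cut_clusters(dendro, k)
            # significant rules are the head of the sorted rule list, so
            # clustering index i maps to position i in result.rules
            labels = {i: sig_labels[i] for i in range(len(significant))}
            (out / "clusters.json").write_text(
                json.dumps(
                    {str(i): lab for i, lab in sorted(labels.items())},
                    indent=1,
                    sort_keys=True,
                )
            )

    with _stage("report"):
        report = build_report(
            result,
            names,
            labels=labels,
            alpha=cfg.enrichment.alpha,
            top=cfg.top_rules,
        )
        if report.rows:
            write_report(report, out / f"report.{cfg.report_format}", cfg.report_format)
        else:
            logger.info("no significant rules; report not written")
    return result, dendro, report
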