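"""Expression loading, gene-level statistics and ranked-list handling.

The pipeline's first stage: load a two-class log2-scale expression matrix,
resolve gene synonyms, compute per-gene log2 fold change (difference of
class means), rank genes by Welch's t statistic or ReliefF, filter by
|logFC| and optionally split into up-/down-regulated lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """Genes x samples matrix of log2-scale expression with two class labels.

    ``class_order`` declares which class is "A": logFC = mean(A) - mean(B).
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    labels: dict[str, str]
    class_order: tuple[str, str]
    replicate_policy: str = "mean"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        missing = [s for s in self.samples if s not in self.labels]
        if missing:
            raise ValidationError(f"samples without class label: {missing}")
        classes = {self.labels[s] for s in self.samples}
        if classes != set(self.class_order) or len(self.class_order) != 2:
            raise ValidationError(
                f"need exactly two classes {self.class_order}, found {sorted(classes)}"
            )
        for c in self.class_order:
            if not any(self.labels[s] == c for s in self.samples):
                raise ValidationError(f"class {c!r} has no samples")

    def class_mask(self, cls: str) -> np.ndarray:
        return np.array([self.labels[s] == cls for s in self.samples])


class RankedGene(NamedTuple):
    gene: str
    score: float
    logfc: float


@dataclass
class RankedGeneList:
    """Genes ordered by a gene-level statistic (descending), carrying logFC."""

    entries: list[RankedGene]
    method: str  # ttest | relieff | precomputed

    def __post_init__(self):
        genes = [e.gene for e in self.entries]
        if len(set(genes)) != len(genes):
            raise ValidationError("ranked list contains duplicate gene ids")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    @property
    def logfc(self) -> dict[str, float]:
        return {e.gene: e.logfc for e in self.entries}

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.entries, columns=["gene", "score", "logfc"])
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path) -> "RankedGeneList":
        df = pd.read_csv(path, sep="\t")
        entries = [
            RankedGene(str(r.gene), float(r.score), float(r.logfc))
            for r in df.itertuples()
        ]
        return cls(entries, method="precomputed")


# -- loading ---------------------------------------------------------------

def _collapse(df: pd.DataFrame, policy: str) -> pd.DataFrame:
    """Collapse duplicate gene rows (NaN-aware), keeping first-seen order."""
    if df.index.is_unique:
        return df
    if policy == "mean":
        agg = df.groupby(level=0, sort=False).mean()
    elif policy == "median":
        agg = df.groupby(level=0, sort=False).median()
    else:
        raise ValidationError(f"unknown replicate_policy {policy!r}")
    order = pd.unique(df.index)
    return agg.loc[order]


def load_expression(
    expr_path,
    labels_path,
    missing_policy: str = "drop_gene",
    replicate_policy: str = "mean",
    class_order: tuple[str, str] | None = None,
) -> ExpressionDataset:
    """Load expression TSV (first column ``gene``) plus a sample/class TSV.

    Duplicate gene rows are collapsed per ``replicate_policy`` (mean or
    median, NaN-aware); remaining missing cells are handled per
    ``missing_policy`` (drop_gene or mean_impute with the gene's row mean).
    """
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    labels_df = pd.read_csv(labels_path, sep="\t")
    if not {"sample", "class"} <= set(labels_df.columns):
        raise ValidationError("labels file must have 'sample' and 'class' columns")
    labels = dict(zip(labels_df["sample"].astype(str), labels_df["class"].astype(str)))
    samples = [str(c) for c in df.columns]
    unlabeled = [s for s in samples if s not in labels]
    if unlabeled:
        raise ValidationError(f"samples without class label: {unlabeled}")
    classes = sorted({labels[s] for s in samples})
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes, found {classes}")
    if class_order is None:
        class_order = (classes[0], classes[1])

    df = _collapse(df, replicate_policy)
    if df.isna().any().any():
        if missing_policy == "drop_gene":
            df = df.dropna()
        elif missing_policy == "mean_impute":
            row_means = df.mean(axis=1)
            df = df.apply(lambda col: col.fillna(row_means))
            df = df.dropna()  # rows that were entirely missing
        else:
            raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    return ExpressionDataset(
        genes=list(df.index),
        samples=samples,
        values=df.to_numpy(dtype=float),
        labels={s: labels[s] for s in samples},
        class_order=class_order,
        replicate_policy=replicate_policy,
    )


def load_synonyms(path) -> dict[str, str]:
    """Two-column TSV mapping alias -> canonical gene id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return dict(zip(df[0], df[1]))


def resolve_synonyms(
    ds: ExpressionDataset, synonyms: Mapping[str, str]
) -> ExpressionDataset:
    """Replace aliases by canonical ids and collapse resulting duplicates.

    The map is applied entrywise (not transitively).  A cycle of length > 1
    among alias entries is an error; unmapped ids pass through.
    """
    done: set[str] = set()
    for start in synonyms:
        if start in done:
            continue
        path: list[str] = []
        cur = start
        while cur in synonyms and cur not in done:
            if cur in path:
                cycle = path[path.index(cur):]
                if len(cycle) > 1:
                    raise ValidationError(
                        "synonym map contains a cycle: " + " -> ".join(cycle + [cur])
                    )
                break
            path.append(cur)
            cur = synonyms[cur]
        done.update(path)
    new_genes = [synonyms.get(g, g) for g in ds.genes]
    n_mapped = sum(g in synonyms for g in ds.genes)
    if n_mapped:
        logger.info("resolved %d gene synonyms", n_mapped)
    df = pd.DataFrame(ds.values, index=new_genes, columns=ds.samples)
    df = _collapse(df, ds.replicate_policy)
    return ExpressionDataset(
        genes=list(df.index),
        samples=ds.samples,
        values=df.to_numpy(dtype=float),
        labels=dict(ds.labels),
        class_order=ds.class_order,
        replicate_policy=ds.replicate_policy,
    )


# -- gene-level statistics -------------------------------------------------

def compute_logfc(ds: ExpressionDataset) -> dict[str, float]:
    """log2 fold change per gene: mean(class A) - mean(class B)."""
    a = ds.class_mask(ds.class_order[0])
    b = ds.class_mask(ds.class_order[1])
    lfc = ds.values[:, a].mean(axis=1) - ds.values[:, b].mean(axis=1)
    return dict(zip(ds.genes, lfc.tolist()))


def _sorted_entries(genes, scores, lfc) -> list[RankedGene]:
    order = np.argsort(-np.asarray(scores), kind="stable")
    return [RankedGene(genes[i], float(scores[i]), float(lfc[i])) for i in order]


def rank_ttest(ds: ExpressionDataset, pooled: bool = False) -> RankedGeneList:
    """Rank genes by the two-sample t statistic (Welch by default).

    Zero variance in both classes with equal means gives t = 0; with unequal
    means the score is +/-inf, which sorts to the extremes.
    """
    a = ds.class_mask(ds.class_order[0])
    b = ds.class_mask(ds.class_order[1])
    xa, xb = ds.values[:, a], ds.values[:, b]
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValidationError("t-test needs at least 2 samples per class")
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        t = np.where(se == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    return RankedGeneList(_sorted_entries(ds.genes, t, diff), method="ttest")


def rank_relieff(
    ds: ExpressionDataset,
    k_neighbors: int = 5,
    n_iterations: int | None = None,
    seed: int = 0,
) -> RankedGeneList:
    """Rank genes by ReliefF feature weights (samples as instances).

    Features (genes) are min-max normalized; instance distance is Manhattan
    on normalized values.  For each sampled instance the weight of a gene
    decreases with its value differences to the k nearest hits (same class)
    and increases with differences to the k nearest misses.  With
    ``n_iterations`` >= the number of samples every instance is used exactly
    once, which makes the estimate deterministic regardless of seed.
    """
    n_samples = len(ds.samples)
    counts = {c: int(ds.class_mask(c).sum()) for c in ds.class_order}
    if k_neighbors > min(counts.values()) - 1:
        raise ValidationError(
            f"k_neighbors={k_neighbors} exceeds smallest class size minus one "
            f"({min(counts.values()) - 1})"
        )
    if n_iterations is None:
        n_iterations = n_samples
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")

    X = ds.values.T  # samples x genes
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng_span = np.where(hi > lo, hi - lo, 1.0)
    Xn = (X - lo) / rng_span
    Xn[:, hi == lo] = 0.0
    dist = np.abs(Xn[:, None, :] - Xn[None, :, :]).sum(axis=2)

    if n_iterations >= n_samples:
        picks = list(range(n_samples))
    else:
        rng = np.random.default_rng(seed)
        picks = sorted(rng.choice(n_samples, size=n_iterations, replace=False).tolist())
    m = len(picks)

    y = np.array([ds.labels[s] for s in ds.samples])
    w = np.zeros(X.shape[1])
    for i in picks:
        order = np.lexsort((np.arange(n_samples), dist[i]))
        hits = [j for j in order if j != i and y[j] == y[i]][:k_neighbors]
        misses = [j for j in order if y[j] != y[i]][:k_neighbors]
        diff_hits = np.abs(Xn[hits] - Xn[i]).mean(axis=0)
        diff_misses = np.abs(Xn[misses] - Xn[i]).mean(axis=0)
        w += (diff_misses - diff_hits) / m

    a = ds.class_mask(ds.class_order[0])
    b = ds.class_mask(ds.class_order[1])
    lfc = ds.values[:, a].mean(axis=1) - ds.values[:, b].mean(axis=1)
    return RankedGeneList(_sorted_entries(ds.genes, w, lfc), method="relieff")


# -- filtering and splitting ----------------------------------------------

def filter_by_logfc(rl: RankedGeneList, cutoff: float) -> RankedGeneList:
    """Keep entries with |logFC| >= cutoff, preserving rank order."""
    if cutoff < 0:
        raise ValidationError("cutoff must be non-negative")
    return RankedGeneList(
        [e for e in rl.entries if abs(e.logfc) >= cutoff], method=rl.method
    )


def split_up_down(rl: RankedGeneList) -> tuple[RankedGeneList, RankedGeneList]:
    """Partition by logFC sign: (up-regulated, down-regulated).

    The down list is reversed so the most down-regulated gene comes first;
    zero-logFC genes belong to neither list.
    """
    up = [e for e in rl.entries if e.logfc > 0]
    down = [e for e in rl.entries if e.logfc < 0][::-1]
    return RankedGeneList(up, method=rl.method), RankedGeneList(down, method=rl.method)
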