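"""Agglomerative clustering of rules and overlap against reference gene sets.

Rules are encoded as binary membership vectors over the gene universe;
pairwise distances (Euclidean, Manhattan, Hamming, Jaccard) feed a
deterministic agglomerative clustering (Ward, complete, single or average
linkage, Lance-Williams updates, ties broken by the smallest pair of
original rule indices).  The overlap matrix v[i, j] = |Si ∩ Dj| / |Dj|
measures how well rule gene sets cover a reference collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import SegrulesError, ValidationError
from .search import Rule

METRICS = ("euclidean", "manhattan", "hamming", "jaccard")
LINKAGES = ("ward", "complete", "single", "average")


@dataclass
class RuleDistanceMatrix:
    ids: list
    values: np.ndarray
    metric: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("distances must be finite and non-negative")


@dataclass
class Dendrogram:
    """Merge trace of agglomerative clustering.

    Leaves are numbered 0..n-1 in rule order; the i-th merge creates cluster
    id n+i.  Each merge step is (cluster a, cluster b, height) with a < b.
    """

    ids: list
    merges: list[tuple[int, int, float]]
    linkage: str

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class OverlapMatrix:
    rule_ids: list
    ref_ids: list
    values: np.ndarray


def rule_distances(
    rules: Sequence[Rule], universe: Iterable[str], metric: str
) -> RuleDistanceMatrix:
    """Pairwise distances between rules' binary membership vectors."""
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")
    if len(rules) < 2:
        raise ValidationError("need at least two rules")
    uni = sorted(set(universe))
    uni_set = set(uni)
    for i, r in enumerate(rules):
        if not r.covered <= uni_set:
            raise ValidationError(f"rule {i} covers genes outside the universe")
    pos = {g: j for j, g in enumerate(uni)}
    B = np.zeros((len(rules), len(uni)), dtype=np.int64)
    for i, r in enumerate(rules):
        for g in r.covered:
            B[i, pos[g]] = 1
    inter = B @ B.T
    sizes = B.sum(axis=1)
    hamming = sizes[:, None] + sizes[None, :] - 2 * inter
    if metric == "euclidean":
        values = np.sqrt(hamming.astype(float))
    elif metric in ("manhattan", "hamming"):
        values = hamming.astype(float)
    else:  # jaccard
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            values = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(values, 0.0)
    return RuleDistanceMatrix(ids=list(range(len(rules))), values=values, metric=metric)


def _lw_update(linkage, d_ik, d_jk, d_ij, n_i, n_j, n_k):
    """Lance-Williams distance from merged cluster (i u j) to cluster k."""
    if linkage == "single":
        return min(d_ik, d_jk)
    if linkage == "complete":
        return max(d_ik, d_jk)
    if linkage == "average":
        return (n_i * d_ik + n_j * d_jk) / (n_i + n_j)
    # ward (distances assumed euclidean)
    t = n_i + n_j + n_k
    return math.sqrt(
        max(
            ((n_i + n_k) * d_ik**2 + (n_j + n_k) * d_jk**2 - n_k * d_ij**2) / t,
            0.0,
        )
    )


def cluster_rules(dm: RuleDistanceMatrix, linkage: str) -> Dendrogram:
    """Deterministic agglomerative hierarchical clustering.

    At every step the pair of clusters at minimal distance merges; ties —
    including distances equal up to floating-point round-off (relative
    1e-9) — break on the lexicographically smallest (min member index,
    other min member index) pair.  Ward linkage requires Euclidean
    distances.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if linkage == "ward" and dm.metric != "euclidean":
        raise ValidationError("Ward linkage requires euclidean distances")
    n = len(dm.ids)
    if n < 2:
        raise SegrulesError("clustering needs at least two rules")

    dist: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(dm.values[i, j])
    size = {i: 1 for i in range(n)}
    minidx = {i: i for i in range(n)}  # smallest original rule index per cluster
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        dmin = min(dist.values())
        cutoff = dmin + 1e-9 * max(dmin, 1.0)
        best = None
        for pair, d in dist.items():
            if d > cutoff:
                continue
            a, b = sorted(pair, key=lambda c: minidx[c])
            key = (minidx[a], minidx[b])
            if best is None or key < best[0]:
                best = (key, a, b)
        (_key, a, b) = best
        h = dist[frozenset((a, b))]
        merges.append((min(a, b), max(a, b), h))
        new = next_id
        next_id += 1
        for k in active:
            if k in (a, b):
                continue
            d_new = _lw_update(
                linkage,
                dist.pop(frozenset((a, k))),
                dist.pop(frozenset((b, k))),
                h,
                size[a],
                size[b],
                size[k],
            )
            dist[frozenset((new, k))] = d_new
        del dist[frozenset((a, b))]
        active -= {a, b}
        active.add(new)
        size[new] = size[a] + size[b]
        minidx[new] = min(minidx[a], minidx[b])
    return Dendrogram(ids=list(dm.ids), merges=merges, linkage=linkage)


def cut_clusters(d: Dendrogram, k: int) -> dict:
    """Flat k-cluster assignment by undoing the last k-1 merges.

    Labels 1..k are assigned in order of each cluster's smallest member
    rule index; returns rule id -> label.
    """
    n = d.n
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range 1..{n}")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, _h) in enumerate(d.merges[: n - k]):
        members[n + step] = members.pop(a) + members.pop(b)
    clusters = sorted(members.values(), key=min)
    labels: dict = {}
    for label, group in enumerate(clusters, start=1):
        for leaf in group:
            labels[d.ids[leaf]] = label
    return labels


def cluster_gene_sets(
    rules: Sequence[Rule], labels: Mapping
) -> dict[int, tuple[frozenset[str], frozenset[str]]]:
    """Per cluster, the union and intersection of member rules' gene sets."""
    missing = [i for i in range(len(rules)) if i not in labels]
    if missing:
        raise ValidationError(f"labels missing for rules: {missing[:5]}")
    out: dict[int, tuple[frozenset[str], frozenset[str]]] = {}
    by_cluster: dict[int, list[Rule]] = {}
    for i, rule in enumerate(rules):
        by_cluster.setdefault(labels[i], []).append(rule)
    for cl, members in sorted(by_cluster.items()):
        union = frozenset().union(*(r.covered for r in members))
        inter = members[0].covered
        for r in members[1:]:
            inter = inter & r.covered
        out[cl] = (union, inter)
    return out


def overlap_matrix(
    rules: Sequence[Rule], reference: Sequence[tuple[str, Iterable[str]]]
) -> OverlapMatrix:
    """Coverage of reference gene sets by rule gene sets: v = |Si ∩ Dj| / |Dj|."""
    ref = [(sid, frozenset(genes)) for sid, genes in reference]
    for sid, genes in ref:
        if not genes:
            raise ValidationError(f"reference set {sid!r} is empty")
    values = np.zeros((len(rules), len(ref)))
    for i, rule in enumerate(rules):
        for j, (_sid, d) in enumerate(ref):
            values[i, j] = len(rule.covered & d) / len(d)
    return OverlapMatrix(
        rule_ids=list(range(len(rules))),
        ref_ids=[sid for sid, _ in ref],
        values=values,
    )
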