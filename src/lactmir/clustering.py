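"""Agglomerative clustering of miRNA expression patterns.

The three-stage expression vectors are clustered bottom-up with
between-group (unweighted average) linkage: the distance between two
clusters is the mean of all cross-pair distances.  The implementation keeps
the full merge history and breaks distance ties deterministically on the
lexicographically smallest cluster representatives, so a given input always
yields the same dendrogram.  Cluster labels A, B, ... are assigned in order
of descending mean expression at the earliest stage, mirroring the usual
presentation of lactation-stage profiles, and single miRNAs can be manually
reassigned afterwards (recorded, not silent).
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "ClusterAssignment",
    "compute_distances",
    "agglomerate",
    "cut_tree",
    "apply_overrides",
]

MergeHistory = list[tuple[frozenset, frozenset, float]]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match id list")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        if (v < 0).any() or not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")


@dataclass
class ClusterAssignment:
    labels: dict[str, str]
    merge_history: MergeHistory = field(default_factory=list)
    overrides_applied: list[tuple[str, str, str]] = field(default_factory=list)

    def members(self, label: str) -> list[str]:
        return sorted(m for m, lab in self.labels.items() if lab == label)

    def cluster_labels(self) -> list[str]:
        return sorted(set(self.labels.values()))


def compute_distances(
    profile: pd.DataFrame,
    metric: str = "sqeuclidean",
    rescale: bool = False,
) -> DistanceMatrix:
    """Pairwise distances between per-miRNA stage-expression vectors.

    metric : "sqeuclidean" (default) or "euclidean"
    rescale : divide each miRNA's vector by its own maximum first, which
        compares pattern shapes rather than absolute abundance
    """
    if profile.isna().any().any():
        raise ValueError("every miRNA needs a value for every stage")
    X = profile.to_numpy(dtype="float64")
    ids = [str(i) for i in profile.index]
    if rescale:
        peak = X.max(axis=1, keepdims=True)
        peak[peak == 0] = 1.0
        X = X / peak
    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    if metric == "sqeuclidean":
        values = d2
    elif metric == "euclidean":
        values = np.sqrt(d2)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids=ids, values=values)


def agglomerate(d: DistanceMatrix) -> MergeHistory:
    """Full between-group-linkage merge history (n-1 merges).

    Cluster distances are maintained with the Lance-Williams average-linkage
    update d(a+b, k) = (|a| d(a,k) + |b| d(b,k)) / (|a|+|b|).  When several
    pairs attain the minimum distance, the pair whose (sorted) cluster
    representatives — each cluster's smallest member id — compare smallest
    wins, making the history deterministic.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("need at least 2 items to agglomerate")
    # cluster state keyed by representative (smallest member id)
    members: dict[str, frozenset] = {i: frozenset([i]) for i in d.ids}
    index = {i: k for k, i in enumerate(d.ids)}
    dist: dict[frozenset, float] = {}
    for a, b in itertools.combinations(d.ids, 2):
        dist[frozenset((a, b))] = float(d.values[index[a], index[b]])

    history: MergeHistory = []
    while len(members) > 1:
        best = None
        for a, b in itertools.combinations(sorted(members), 2):
            key = (dist[frozenset((a, b))], a, b)
            if best is None or key < best:
                best = key
        height, a, b = best
        ca, cb = members.pop(a), members.pop(b)
        rep = min(a, b)
        merged = ca | cb
        for other in members:
            pair_a = frozenset((a, other))
            pair_b = frozenset((b, other))
            new = (len(ca) * dist.pop(pair_a) + len(cb) * dist.pop(pair_b)) / len(merged)
            dist[frozenset((rep, other))] = new
        dist.pop(frozenset((a, b)))
        members[rep] = merged
        history.append((ca, cb, height))
    return history


def _labels_for(k: int) -> list[str]:
    letters = list(string.ascii_uppercase)
    if k <= len(letters):
        return letters[:k]
    extra = ["".join(p) for p in itertools.product(letters, repeat=2)]
    return (letters + extra)[:k]


def cut_tree(
    history: MergeHistory,
    k: int,
    profile: pd.DataFrame | None = None,
) -> ClusterAssignment:
    """Partition into k clusters by undoing the last k-1 merges.

    With ``profile`` given, clusters are labelled A, B, ... in order of
    descending mean expression at the earliest stage (first column), ties
    then alphabetically by first member; without it, alphabetically by
    first member only.
    """
    items = sorted(history[0][0] | history[0][1] | frozenset().union(*(a | b for a, b, _ in history)))
    n = len(items)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    clusters: list[set] = [set([i]) for i in items]
    for ca, cb, _ in history[: n - k]:
        merged = ca | cb
        clusters = [c for c in clusters if not c <= merged]
        clusters.append(set(merged))
    assert len(clusters) == k

    def sort_key(cluster: set):
        first = min(cluster)
        if profile is not None:
            early = profile.columns[0]
            mean_early = float(np.mean([profile.at[m, early] for m in cluster]))
            return (-mean_early, first)
        return (first,)

    ordered = sorted(clusters, key=sort_key)
    labels: dict[str, str] = {}
    for lab, cluster in zip(_labels_for(k), ordered):
        for m in cluster:
            labels[m] = lab
    return ClusterAssignment(labels=labels, merge_history=list(history))


def apply_overrides(
    assignment: ClusterAssignment,
    overrides: list[tuple[str, str]],
) -> ClusterAssignment:
    """Reassign named miRNAs to existing cluster labels, keeping a record."""
    labels = dict(assignment.labels)
    applied = list(assignment.overrides_applied)
    valid = set(labels.values())
    for mirna, target in overrides:
        if mirna not in labels:
            raise ValueError(f"unknown miRNA {mirna!r}")
        if target not in valid:
            raise ValueError(f"unknown cluster label {target!r}; have {sorted(valid)}")
        applied.append((mirna, labels[mirna], target))
        labels[mirna] = target
    return ClusterAssignment(
        labels=labels,
        merge_history=list(assignment.merge_history),
        overrides_applied=applied,
    )
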