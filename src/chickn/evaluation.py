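"""Clustering quality metrics: Rand index, precision/recall, Davies-Bouldin.

Pair-based external metrics compare an obtained partition U against a ground
truth V over all C(N,2) element pairs; the internal Davies-Bouldin index
scores a clustering without ground truth, using the same W1 distance as the
clustering itself (between raw chromatograms and consensus chromatograms).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .kernel import w1_distance

__all__ = [
    "EvalReport",
    "pair_counts",
    "rand_index",
    "precision_recall",
    "db_index",
]


@dataclass
class EvalReport:
    rand_index: float | None = None
    precision: float | None = None
    recall: float | None = None
    db_index: float | None = None
    TP: int | None = None
    TN: int | None = None
    FP: int | None = None
    FN: int | None = None
    within_distances: list | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _contingency(U, V):
    u = np.asarray(U)
    v = np.asarray(V)
    if u.shape != v.shape:
        raise ValueError("partitions must label the same element set")
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    table = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return table


def pair_counts(U, V) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) pair counts of partition U against ground truth V.

    TP: pairs together in both; TN: apart in both; FP: together in U only;
    FN: together in V only.  Computed from the contingency table.
    """
    table = _contingency(U, V)
    n = int(table.sum())
    pairs_total = comb(n, 2)
    same_both = int(sum(comb(int(x), 2) for x in table.ravel()))
    same_u = int(sum(comb(int(x), 2) for x in table.sum(axis=1)))
    same_v = int(sum(comb(int(x), 2) for x in table.sum(axis=0)))
    TP = same_both
    FP = same_u - same_both
    FN = same_v - same_both
    TN = pairs_total - TP - FP - FN
    return TP, TN, FP, FN


def rand_index(U, V) -> float:
    """(TP + TN) / C(N,2): fraction of correctly clustered pairs, in [0,1]."""
    TP, TN, FP, FN = pair_counts(U, V)
    return (TP + TN) / (TP + TN + FP + FN)


def precision_recall(U, V) -> tuple[float | None, float | None]:
    """Pairwise precision TP/(TP+FP) and recall TP/(TP+FN).

    A zero denominator makes the corresponding value undefined; ``None`` is
    returned rather than silently reporting 0.
    """
    TP, TN, FP, FN = pair_counts(U, V)
    precision = TP / (TP + FP) if (TP + FP) > 0 else None
    recall = TP / (TP + FN) if (TP + FN) > 0 else None
    return precision, recall


def db_index(clusters: list[np.ndarray], consensus: list[np.ndarray]) -> float:
    """Davies-Bouldin index with W1 distances in the chromatogram space.

    ``clusters[j]`` is the member chromatogram block (rows x size_j) of
    cluster j and ``consensus[j]`` its input-space centroid (the neighborhood
    -mean consensus chromatogram).  Smaller is better.
    """
    k = len(clusters)
    if k < 2:
        raise ValueError("DB index needs at least 2 non-empty clusters")
    if len(consensus) != k:
        raise ValueError("one consensus chromatogram per cluster required")

    S = np.empty(k)
    for j, (block, c) in enumerate(zip(clusters, consensus)):
        block = np.atleast_2d(np.asarray(block, dtype=float).T).T
        if block.shape[1] == 0:
            raise ValueError(f"cluster {j} is empty")
        S[j] = np.mean([w1_distance(block[:, i], c) for i in range(block.shape[1])])

    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = w1_distance(consensus[i], consensus[j])
            if d == 0:
                raise ValueError(
                    f"coincident consensus chromatograms for clusters {i} and {j}"
                )
            D[i, j] = D[j, i] = d

    ratios = np.zeros(k)
    for i in range(k):
        others = [j for j in range(k) if j != i]
        ratios[i] = max((S[i] + S[j]) / D[i, j] for j in others)
    return float(ratios.mean())


def evaluate(
    labels,
    truth=None,
    clusters=None,
    consensus=None,
    exclude_truth_labels=(-1, 0),
) -> EvalReport:
    """Full evaluation report; external metrics need truth, DB needs clusters.

    Elements whose ground-truth label is in ``exclude_truth_labels`` (noise)
    are dropped before pair counting.
    """
    report = EvalReport()
    if truth is not None:
        labels = np.asarray(labels)
        truth = np.asarray(truth)
        keep = ~np.isin(truth, list(exclude_truth_labels))
        TP, TN, FP, FN = pair_counts(labels[keep], truth[keep])
        report.TP, report.TN, report.FP, report.FN = TP, TN, FP, FN
        total = TP + TN + FP + FN
        report.rand_index = (TP + TN) / total if total else None
        report.precision = TP / (TP + FP) if (TP + FP) > 0 else None
        report.recall = TP / (TP + FN) if (TP + FN) > 0 else None
    if clusters is not None and consensus is not None and len(clusters) >= 2:
        report.db_index = db_index(clusters, consensus)
    return report
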