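"""Divisive hierarchical compressive clustering of chromatogram matrices.

The pipeline (CHICKN): derive sizes from (N, k, k_total) -> fit a Nyström
feature map on l ~ sqrt(N) landmarks -> estimate the kernel bandwidth gamma
from landmark nearest-neighbor distances -> estimate the frequency scale
sigma^2 -> sample one frequency set -> sketch the full dataset -> compressive
k-means into k clusters -> assign every column to its closest centroid ->
recurse into each cluster, re-sketching only its columns with the *same*
frequencies and Nyström model, until depth T or the cluster is too small.
Leaves receive consensus chromatograms by neighborhood-mean pre-images.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .ckm import CentroidSet, ckm_fit
from .compression import (
    FrequencySet,
    NystromModel,
    estimate_sigma2,
    nystrom_fit,
    sample_frequencies,
    sketch,
)
from .kernel import KernelConfig, estimate_gamma

__all__ = [
    "HierarchyConfig",
    "ClusterNode",
    "ClusterTree",
    "Assignment",
    "ConsensusChromatogram",
    "derive_parameters",
    "assign",
    "preimage",
    "chickn_run",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HierarchyConfig:
    """Divisive clustering configuration.

    k: branching factor per level; k_total: upper bound on leaf count;
    nu: neighborhood size for bandwidth estimation and pre-images;
    min_split_size: smallest cluster still eligible for splitting.
    """

    k: int = 2
    k_total: int = 8
    nu: int = 32
    min_split_size: int | None = None  # defaults to nu
    p: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.k_total < self.k:
            raise ValueError("k_total must be >= k")

    @property
    def T(self) -> int:
        return _int_log_floor(self.k_total, self.k)


def _int_log_floor(k_total: int, k: int) -> int:
    """Largest T with k**T <= k_total (exact integer arithmetic)."""
    t, power = 0, 1
    while power * k <= k_total:
        power *= k
        t += 1
    return t


def derive_parameters(N: int, k: int, k_total: int) -> dict:
    """Derive compression sizes from the dataset size and cluster counts.

    l = ceil(sqrt(N)) landmarks, s = ceil(sqrt(k) * N^(1/4)) target rank,
    m = ceil(k^(3/2) * N^(1/4)) sketch length, T = floor(log_k(k_total))
    hierarchy depth.  The ceiling convention is used throughout.
    """
    if N < 4:
        raise ValueError("N must be >= 4")
    if k < 2 or k_total < k:
        raise ValueError("require k >= 2 and k_total >= k")
    l = int(np.ceil(np.sqrt(N)))
    s = int(np.ceil(np.sqrt(k) * N**0.25))
    m = int(np.ceil(k**1.5 * N**0.25))
    return {"l": l, "s": s, "m": m, "T": _int_log_floor(k_total, k)}


@dataclass
class ClusterNode:
    node_id: int
    level: int
    parent: int | None
    members: np.ndarray
    centroid: np.ndarray | None = None  # feature-space centroid
    children: list[int] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterTree:
    nodes: dict[int, ClusterNode]
    root: int = 0

    @property
    def leaves(self) -> list[ClusterNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    def to_json(self) -> str:
        return json.dumps(
            {
                str(nid): {
                    "level": n.level,
                    "parent": n.parent,
                    "size": int(len(n.members)),
                    "children": n.children,
                }
                for nid, n in self.nodes.items()
            },
            indent=2,
        )


@dataclass
class Assignment:
    """Leaf label and winning-centroid similarity per chromatogram column."""

    labels: np.ndarray
    similarities: np.ndarray


@dataclass
class ConsensusChromatogram:
    """Input-space consensus profile of a leaf cluster (pre-image solution)."""

    intensity: np.ndarray
    cluster_id: int
    q: int


def assign(
    matrix,
    column_indices: np.ndarray,
    model: NystromModel,
    centroids: CentroidSet | np.ndarray,
    chunk: int = 2048,
) -> Assignment:
    """Label each column with the centroid maximizing <phi~(x), c/||c||>.

    Ties go to the lowest centroid index.  Columns are streamed in chunks.
    """
    C = centroids.centroids if isinstance(centroids, CentroidSet) else np.atleast_2d(centroids)
    norms = np.linalg.norm(C, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm centroid cannot be used for assignment")
    C_unit = C / norms[:, None]
    idx = np.asarray(column_indices)
    labels = np.empty(idx.size, dtype=int)
    sims = np.empty(idx.size)
    for start in range(0, idx.size, chunk):
        sub = idx[start:start + chunk]
        cols = (
            matrix.columns(sub)
            if hasattr(matrix, "columns")
            else np.asarray(matrix)[:, sub]
        )
        scores = model.embed(cols) @ C_unit.T  # B x k
        labels[start:start + len(sub)] = np.argmax(scores, axis=1)  # first max wins
        sims[start:start + len(sub)] = scores[np.arange(len(sub)), labels[start:start + len(sub)]]
    return Assignment(labels=labels, similarities=sims)


def preimage(
    matrix,
    member_indices: np.ndarray,
    centroid: np.ndarray,
    model: NystromModel,
    nu: int = 32,
    cluster_id: int = -1,
) -> ConsensusChromatogram | None:
    """Neighborhood-mean consensus chromatogram of a cluster.

    q = min(nu, cluster size) members with the highest similarity
    <phi~(x), c/||c||> to the centroid are averaged in the input space.
    Returns None for an empty cluster (no consensus exists).
    """
    members = np.asarray(member_indices)
    if members.size == 0:
        return None
    q = min(nu, members.size)
    cols = (
        matrix.columns(members)
        if hasattr(matrix, "columns")
        else np.asarray(matrix)[:, members]
    )
    c_unit = centroid / np.linalg.norm(centroid)
    sims = model.embed(cols) @ c_unit
    top = np.argsort(-sims, kind="stable")[:q]
    return ConsensusChromatogram(
        intensity=cols[:, top].mean(axis=1), cluster_id=cluster_id, q=q
    )


def chickn_run(
    matrix,
    cfg: HierarchyConfig,
    kernel_cfg: KernelConfig | None = None,
    gamma: float | None = None,
    reciprocal_gamma: bool = True,
):
    """Run the full divisive compressive clustering pipeline.

    Returns ``(tree, assignment, consensus, manifest)`` where consensus maps
    leaf node ids to :class:`ConsensusChromatogram` and manifest records all
    derived parameters, the estimated gamma and sigma^2, and the seed.

    gamma (and the whole ``kernel_cfg``) may be supplied explicitly; by
    default gamma is estimated once, from the level-0 Nyström landmarks, and
    reused at every level, as is the single frequency set.  The pipeline uses
    the reciprocal-mean bandwidth (gamma ~ 1 / mean nearest-neighbor d^p) so
    that similarities decay on the scale of the data's own distances; see the
    methods note for the rationale.
    """
    N = matrix.n_columns if hasattr(matrix, "n_columns") else matrix.shape[1]
    params = derive_parameters(N, cfg.k, cfg.k_total)
    l, s, m, T = params["l"], params["s"], params["m"], params["T"]
    r = max(l // 2, 1)
    s = min(s, r)
    min_split = cfg.min_split_size if cfg.min_split_size is not None else cfg.nu

    root_ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(x) for x in root_ss.generate_state(4) >> 1]  # keep < 2^31

    # landmarks first: gamma is estimated from their pairwise W1 distances
    rng = np.random.default_rng(seeds[0])
    landmark_indices = np.sort(rng.choice(N, size=l, replace=False))
    landmark_cols = (
        matrix.columns(landmark_indices)
        if hasattr(matrix, "columns")
        else np.asarray(matrix)[:, landmark_indices]
    )
    if kernel_cfg is None:
        if gamma is None:
            gamma = estimate_gamma(
                landmark_cols, nu=min(cfg.nu, l - 1), p=cfg.p,
                reciprocal=reciprocal_gamma,
            )
        kernel_cfg = KernelConfig(p=cfg.p, gamma=gamma, nu=cfg.nu)

    model = nystrom_fit(
        matrix, l=l, r=r, s=s, cfg=kernel_cfg,
        landmark_indices=landmark_indices,
    )
    sigma2 = estimate_sigma2(model, matrix, subsample_size=min(1000, N), seed=seeds[1])
    freqs = sample_frequencies(m, s, sigma2, seed=seeds[2])
    landmark_embeddings = model.embed(landmark_cols)

    tree = ClusterTree(nodes={0: ClusterNode(0, 0, None, np.arange(N))})
    next_id = 1
    frontier = [0]
    split_rng = np.random.default_rng(seeds[3])

    while frontier:
        node_id = frontier.pop(0)
        node = tree.nodes[node_id]
        if node.level >= T or len(node.members) < max(min_split, cfg.k):
            continue
        if len(tree.leaves) - 1 + cfg.k > cfg.k_total:
            continue  # splitting would exceed the leaf budget
        try:
            sub_sketch = sketch(matrix, node.members, model, freqs)
            # candidate initializations come from the node's own members
            # (global landmarks may lie outside the cluster being re-split)
            n_init = min(64, len(node.members))
            init_ids = node.members[
                split_rng.choice(len(node.members), size=n_init, replace=False)
            ]
            init_cols = (
                matrix.columns(init_ids)
                if hasattr(matrix, "columns")
                else np.asarray(matrix)[:, init_ids]
            )
            init_points = model.embed(init_cols)
            # CKM can land in local minima (e.g. all members captured by one
            # centroid); run a few restarts and keep the lowest-objective
            # solution that actually splits the node
            sub_assign = centroids = None
            best_obj = np.inf
            for _attempt in range(3):
                ckm_seed = int(split_rng.integers(2**31))
                cand = ckm_fit(sub_sketch, freqs, cfg.k, init_points, seed=ckm_seed)
                cand_assign = assign(matrix, node.members, model, cand)
                n_children = np.count_nonzero(
                    np.bincount(cand_assign.labels, minlength=cfg.k)
                )
                if n_children >= 2 and cand.objective < best_obj:
                    centroids, sub_assign, best_obj = cand, cand_assign, cand.objective
        except Exception as exc:  # failed split: keep parent as leaf
            logger.warning("split of node %d failed (%s); kept as leaf", node_id, exc)
            continue
        if sub_assign is None:
            logger.warning(
                "degenerate split of node %d (all members to one centroid); kept as leaf",
                node_id,
            )
            continue
        for j in range(cfg.k):
            members_j = node.members[sub_assign.labels == j]
            if members_j.size == 0:
                continue  # empty clusters are allowed but not materialized
            child = ClusterNode(
                next_id, node.level + 1, node_id, members_j,
                centroid=centroids.centroids[j],
            )
            tree.nodes[next_id] = child
            node.children.append(next_id)
            frontier.append(next_id)
            next_id += 1

    # final assignment: every column goes to the most similar leaf centroid
    # (the per-level routing can strand borderline columns in a neighboring
    # subtree; one global similarity argmax over the final centroid set
    # repairs that); leaves left empty by the reassignment are allowed
    centroid_leaves = [n for n in tree.leaves if n.centroid is not None]
    labels = np.empty(N, dtype=int)
    sims = np.full(N, np.nan)
    if len(centroid_leaves) >= 2:
        C = np.vstack([n.centroid for n in centroid_leaves])
        ga = assign(matrix, np.arange(N), model, C)
        for j, leaf in enumerate(centroid_leaves):
            leaf.members = np.flatnonzero(ga.labels == j)
        labels = np.array([centroid_leaves[j].node_id for j in ga.labels])
        sims = ga.similarities
    else:
        for leaf in tree.leaves:
            labels[leaf.members] = leaf.node_id

    consensus: dict[int, ConsensusChromatogram] = {}
    for leaf in tree.leaves:
        if leaf.members.size == 0:
            continue
        centroid = (
            leaf.centroid
            if leaf.centroid is not None
            else landmark_embeddings.mean(axis=0)  # root never split
        )
        cons = preimage(
            matrix, leaf.members, centroid, model,
            nu=cfg.nu, cluster_id=leaf.node_id,
        )
        if cons is not None:
            consensus[leaf.node_id] = cons

    assignment = Assignment(labels=labels, similarities=sims)
    _check_partition(tree, N)
    manifest = {
        "N": int(N), "k": cfg.k, "k_total": cfg.k_total,
        "l": l, "r": r, "s": s, "m": m, "T": T,
        "nu": cfg.nu, "min_split_size": min_split,
        "p": kernel_cfg.p, "gamma": kernel_cfg.gamma, "sigma2": sigma2,
        "seed": cfg.seed,
    }
    return tree, assignment, consensus, manifest


def _check_partition(tree: ClusterTree, N: int) -> None:
    counts = np.zeros(N, dtype=int)
    for leaf in tree.leaves:
        counts[leaf.members] += 1
    if not np.all(counts == 1):
        raise AssertionError("leaves do not partition the columns")
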