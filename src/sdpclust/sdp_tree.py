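"""Ab-initio specificity grouping by stochastic co-assignment.

Without prior group labels, the pipeline repeatedly (default 10000
times) seeds the refinement with small random training groups, records
for every sequence pair how often they end up in the same refined
group, and converts the co-assignment frequency into a distance

    d(i, j) = -log(#co-assigned / runs).

A UPGMA tree is built on these distances and cut into clusters by a
dynamic programme over the per-clade quality

    Q(X) = min{d_ij : i in X, j not in X} - diam(X),

which selects the tree-consistent partition whose sorted quality vector
is lexicographically maximal.  A final SDP pass on the resulting
clusters yields the reported SDP set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .mi_moments import MomentTable
from .msa_io import Alignment, GroupAssignment
from .sdp_group import DEFAULT_MAX_ITER, RefineEngine
from .sdp_scoring import (
    SDPPrediction,
    empty_prediction,
    score_columns,
    select_sdps,
)

logger = logging.getLogger(__name__)

DEFAULT_RUNS = 10000
DEFAULT_GROUP_SIZE = 3
DEFAULT_RESTARTS = 6
#: During stochastic exploration the refinement always works with the
#: least probable column set, without a significance ceiling; only the
#: final reported SDP set is gated.
DEFAULT_REFINE_ALPHA = 1.0


@dataclass(frozen=True)
class CoassignmentMatrix:
    """Pairwise counts of co-grouping events over resampling runs."""

    ids: tuple[str, ...]
    counts: np.ndarray  # (N, N) int, symmetric, diagonal = runs
    runs: int


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray


@dataclass
class TreeNode:
    """Node of a rooted UPGMA tree; leaves carry a single index."""

    height: float
    leaves: tuple[int, ...]  # sorted leaf indices of the subtree
    children: tuple["TreeNode", "TreeNode"] | None = None
    quality: float = field(default=float("nan"))
    quality_max: float = field(default=float("nan"))

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class ClusterTree:
    """Rooted binary UPGMA tree over sequence leaves."""

    root: TreeNode
    ids: tuple[str, ...]

    def nodes(self) -> Iterator[TreeNode]:
        """Post-order traversal (children before parents)."""
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if node.is_leaf or expanded:
                yield node
            else:
                stack.append((node, True))
                stack.append((node.children[1], False))
                stack.append((node.children[0], False))

    def to_newick(self) -> str:
        def render(node: TreeNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"{self.ids[node.leaves[0]]}:{length:.10g}"
            left = render(node.children[0], node.height)
            right = render(node.children[1], node.height)
            return f"({left},{right}):{length:.10g}"

        if self.root.is_leaf:
            return f"{self.ids[self.root.leaves[0]]}:0;"
        left = render(self.root.children[0], self.root.height)
        right = render(self.root.children[1], self.root.height)
        return f"({left},{right});"


@dataclass(frozen=True)
class Clustering:
    """Disjoint clusters (clades of the tree) covering all sequences."""

    ids: tuple[str, ...]
    clusters: tuple[tuple[int, ...], ...]
    qualities: tuple[float, ...]

    def to_grouping(self, alignment: Alignment) -> GroupAssignment:
        """Clusters as specificity groups, labelled C1.. by lowest member."""
        order = sorted(range(len(self.clusters)), key=lambda c: self.clusters[c][0])
        labels: list[Optional[str]] = [None] * len(self.ids)
        for rank, c in enumerate(order, 1):
            for i in self.clusters[c]:
                labels[i] = f"C{rank}"
        return GroupAssignment(ids=alignment.ids, labels=tuple(labels))


@dataclass(frozen=True)
class SDPclustResult:
    """Full output of the ab-initio pipeline."""

    grouping: GroupAssignment
    sdps: SDPPrediction
    tree: ClusterTree
    distances: DistanceMatrix
    coassignment: CoassignmentMatrix
    clustering: Clustering


def default_n_groups(n_sequences: int) -> int:
    """Number of random training groups: roughly N/10, at least 2."""
    return max(2, round(n_sequences / 10))


def sample_training_grouping(
    alignment: Alignment,
    rng: np.random.Generator,
    group_size: int = DEFAULT_GROUP_SIZE,
    n_groups: Optional[int] = None,
) -> GroupAssignment:
    """Randomly draw disjoint equal-size training groups; rest virtual."""
    n = alignment.n_sequences
    g = default_n_groups(n) if n_groups is None else n_groups
    if g < 2:
        raise ValueError("need at least 2 training groups")
    if n < 2 * group_size:
        raise ValueError(f"alignment too small for groups of {group_size}")
    if g * group_size > n:
        raise ValueError("g * group_size exceeds the number of sequences")
    chosen = rng.choice(n, size=g * group_size, replace=False)
    labels: list[Optional[str]] = [None] * n
    for j in range(g):
        for i in chosen[j * group_size : (j + 1) * group_size]:
            labels[i] = f"T{j + 1}"
    return GroupAssignment(ids=alignment.ids, labels=tuple(labels))


def _sample_gidx(
    n: int, rng: np.random.Generator, group_size: int, g: int
) -> np.ndarray:
    chosen = rng.choice(n, size=g * group_size, replace=False)
    gidx = np.full(n, -1, dtype=np.int64)
    for j in range(g):
        gidx[chosen[j * group_size : (j + 1) * group_size]] = j
    return gidx


def accumulate_coassignment(
    alignment: Alignment,
    table: Optional[MomentTable] = None,
    runs: int = DEFAULT_RUNS,
    seed: int | np.random.SeedSequence = 0,
    group_size: int = DEFAULT_GROUP_SIZE,
    n_groups: Optional[int] = None,
    max_iter: int = DEFAULT_MAX_ITER,
    restarts: int = DEFAULT_RESTARTS,
    engine: Optional[RefineEngine] = None,
) -> CoassignmentMatrix:
    """Count, over many refined random seeds, how often pairs co-group.

    Each run draws ``restarts`` independent random training groupings,
    refines each, and keeps the refined state whose SDP set is the most
    significant per column (the mean log set-probability per selected
    position); the pair counts within every final real group of that
    state are incremented.  Virtual membership never counts.  Runs use
    independent child seeds derived from the master seed, so results
    are reproducible.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    n = alignment.n_sequences
    g = default_n_groups(n) if n_groups is None else n_groups
    if engine is None:
        engine = RefineEngine(alignment, table=table, k_max=g)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    counts = np.zeros((n, n), dtype=np.int64)
    for child in ss.spawn(runs):
        rng = np.random.default_rng(child)
        best_quality = np.inf
        best_gidx = None
        for _ in range(restarts):
            gidx0 = _sample_gidx(n, rng, group_size, g)
            gidx, _, sdp_cols0, log_p, _, _ = engine.refine(
                gidx0, max_iter=max_iter
            )
            quality = log_p / sdp_cols0.size if sdp_cols0.size else 0.0
            if quality < best_quality:
                best_quality = quality
                best_gidx = gidx
        for j in range(int(best_gidx.max()) + 1):
            members = np.nonzero(best_gidx == j)[0]
            if members.size > 1:
                counts[np.ix_(members, members)] += 1
    np.fill_diagonal(counts, runs)
    return CoassignmentMatrix(ids=alignment.ids, counts=counts, runs=runs)


def coassignment_to_distance(cm: CoassignmentMatrix) -> DistanceMatrix:
    """d_ij = -log(counts_ij / runs); zero counts capped at -log 1/(runs+1)."""
    r = cm.runs
    cap = -np.log(1.0 / (r + 1))
    with np.errstate(divide="ignore"):
        d = -np.log(cm.counts / r)
    d = np.where(np.isinf(d), cap, d)
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=cm.ids, values=d)


def upgma(dist: DistanceMatrix) -> ClusterTree:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    Node heights are half the merge distance.  Merge ties are broken by
    the lexicographically smallest pair of minimal leaf indices, making
    the tree deterministic for any input.
    """
    d = np.asarray(dist.values, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("UPGMA needs at least 2 leaves")
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    active: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, leaves=(i,)) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    work = d.copy().astype(float)
    next_id = n
    ids_alive = list(range(n))
    # dist between current clusters kept in a dict-of-dict via matrix rows
    cur = {i: {j: work[i, j] for j in range(n) if j != i} for i in range(n)}
    while len(ids_alive) > 1:
        best = None
        for ai in range(len(ids_alive)):
            for bi in range(ai + 1, len(ids_alive)):
                a, b = ids_alive[ai], ids_alive[bi]
                dij = cur[a][b]
                tie_key = tuple(sorted((active[a].leaves[0], active[b].leaves[0])))
                cand = (dij, tie_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dij, _, a, b = best
        node = TreeNode(
            height=dij / 2.0,
            leaves=tuple(sorted(active[a].leaves + active[b].leaves)),
            children=(active[a], active[b]),
        )
        merged: dict[int, float] = {}
        for c in ids_alive:
            if c in (a, b):
                continue
            merged[c] = (sizes[a] * cur[a][c] + sizes[b] * cur[b][c]) / (
                sizes[a] + sizes[b]
            )
        for c in ids_alive:
            if c in (a, b):
                continue
            del cur[c][a]
            del cur[c][b]
            cur[c][next_id] = merged[c]
        cur[next_id] = merged
        del cur[a], cur[b]
        active[next_id] = node
        sizes[next_id] = sizes[a] + sizes[b]
        del active[a], active[b], sizes[a], sizes[b]
        ids_alive = [c for c in ids_alive if c not in (a, b)] + [next_id]
        next_id += 1
    return ClusterTree(root=active[ids_alive[0]], ids=dist.ids)


def cluster_quality(leaves: Sequence[int], d: np.ndarray) -> float:
    """Q(X) = min external distance - internal diameter.

    Singletons have internal diameter 0.  The full leaf set has no
    external distance; it returns -inf so the dynamic programme never
    prefers the trivial one-cluster solution over its children.
    """
    idx = np.asarray(sorted(leaves), dtype=np.int64)
    n = d.shape[0]
    if idx.size == 0:
        raise ValueError("empty cluster")
    outside = np.setdiff1d(np.arange(n), idx, assume_unique=True)
    if outside.size == 0:
        return float("-inf")
    q_ext = float(d[np.ix_(idx, outside)].min())
    q_int = 0.0 if idx.size == 1 else float(d[np.ix_(idx, idx)].max())
    return q_ext - q_int


def best_tree_clustering(tree: ClusterTree, dist: DistanceMatrix) -> Clustering:
    """Cut the tree into the lexicographically best set of clades.

    Bottom-up, ``Q_max(X) = max(Q(X), min(Q_max(left), Q_max(right)))``
    with ``Q_max = Q`` at leaves; top-down, the shallowest node with
    ``Q(X) = Q_max(X)`` on each path is emitted as a cluster.  The
    resulting partition maximises the ascending-sorted vector of
    cluster qualities lexicographically among all tree-consistent
    partitions (shorter vectors compare as if padded with +inf).
    """
    d = dist.values
    for node in tree.nodes():
        node.quality = cluster_quality(node.leaves, d)
        if node.is_leaf:
            node.quality_max = node.quality
        else:
            child_min = min(c.quality_max for c in node.children)
            node.quality_max = max(node.quality, child_min)
    clusters: list[tuple[int, ...]] = []
    qualities: list[float] = []

    def descend(node: TreeNode) -> None:
        if node.quality == node.quality_max:
            clusters.append(node.leaves)
            qualities.append(node.quality)
            return
        for child in node.children:
            descend(child)

    descend(tree.root)
    return Clustering(
        ids=tree.ids, clusters=tuple(clusters), qualities=tuple(qualities)
    )


def run_sdpclust(
    alignment: Alignment,
    runs: int = DEFAULT_RUNS,
    seed: int = 0,
    group_size: int = DEFAULT_GROUP_SIZE,
    n_groups: Optional[int] = None,
    max_iter: int = DEFAULT_MAX_ITER,
    restarts: int = DEFAULT_RESTARTS,
    table: Optional[MomentTable] = None,
) -> SDPclustResult:
    """Full ab-initio pipeline: resample, cluster, and report SDPs.

    Runs the co-assignment resampling, converts it to distances, builds
    the UPGMA tree, cuts it by the quality DP, then treats the clusters
    as specificity groups for one final SDP pass.
    """
    if alignment.n_sequences < 4:
        raise ValueError("ab-initio clustering needs at least 4 sequences")
    g = default_n_groups(alignment.n_sequences) if n_groups is None else n_groups
    engine = RefineEngine(alignment, table=table, k_max=g, alpha=DEFAULT_REFINE_ALPHA)
    cm = accumulate_coassignment(
        alignment,
        runs=runs,
        seed=seed,
        group_size=group_size,
        n_groups=g,
        max_iter=max_iter,
        restarts=restarts,
        engine=engine,
    )
    dist = coassignment_to_distance(cm)
    tree = upgma(dist)
    clustering = best_tree_clustering(tree, dist)
    grouping = clustering.to_grouping(alignment)
    if grouping.k >= 2:
        scores = score_columns(alignment, grouping, table=engine.table)
        sdps = select_sdps(scores)
    else:
        logger.warning("clustering produced a single group; no SDP pass possible")
        sdps = empty_prediction()
    return SDPclustResult(
        grouping=grouping,
        sdps=sdps,
        tree=tree,
        distances=dist,
        coassignment=cm,
        clustering=clustering,
    )
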