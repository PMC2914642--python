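"""Resampling, distances, UPGMA and the tree-cut dynamic programme."""

import itertools
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from sdpclust import (
    cluster_quality,
    best_tree_clustering,
    coassignment_to_distance,
    run_sdpclust,
    sample_training_grouping,
    upgma,
)
from sdpclust.sdp_tree import CoassignmentMatrix, DistanceMatrix


def dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ids = tuple(ids or (f"s{i}" for i in range(n)))
    return DistanceMatrix(ids=ids, values=values)


# ---------------------------------------------------------------- sampling


def test_training_grouping_defaults(concordant_family):
    aln = concordant_family.alignment
    rng = np.random.default_rng(0)
    g = sample_training_grouping(aln, rng)
    assert g.k == 5  # round(50 / 10)
    assert all(size == 3 for size in g.sizes.values())
    assert sum(lab is None for lab in g.labels) == 35


def test_training_grouping_deterministic_and_disjoint(concordant_family):
    aln = concordant_family.alignment
    g1 = sample_training_grouping(aln, np.random.default_rng(5))
    g2 = sample_training_grouping(aln, np.random.default_rng(5))
    assert g1.labels == g2.labels
    for _ in range(50):
        g = sample_training_grouping(aln, np.random.default_rng())
        members = [sid for sid, lab in zip(g.ids, g.labels) if lab is not None]
        assert len(members) == len(set(members))


def test_training_grouping_too_small(toy_alignment):
    with pytest.raises(ValueError):
        sample_training_grouping(
            toy_alignment, np.random.default_rng(0), group_size=6, n_groups=2
        )


# ---------------------------------------------------------------- distances


def test_coassignment_distance_values():
    counts = np.array([[10000, 10000, 1000], [10000, 10000, 0], [1000, 0, 10000]])
    cm = CoassignmentMatrix(ids=("a", "b", "c"), counts=counts, runs=10000)
    d = coassignment_to_distance(cm).values
    assert d[0, 1] == pytest.approx(0.0)
    assert d[0, 2] == pytest.approx(-math.log(0.1), abs=1e-12)  # 2.302585
    assert d[1, 2] == pytest.approx(-math.log(1 / 10001), abs=1e-12)  # cap
    assert np.all(np.diag(d) == 0)
    assert np.allclose(d, d.T)


# ---------------------------------------------------------------- UPGMA


def test_upgma_two_leaves():
    tree = upgma(dm([[0, 4], [4, 0]]))
    assert tree.root.height == pytest.approx(2.0)
    assert tree.root.leaves == (0, 1)


def test_upgma_three_leaves_average_linkage():
    d = [[0, 2, 6], [2, 0, 6], [6, 6, 0]]
    tree = upgma(dm(d))
    assert tree.root.height == pytest.approx(3.0)
    inner = [c for c in tree.root.children if not c.is_leaf][0]
    assert inner.leaves == (0, 1)
    assert inner.height == pytest.approx(1.0)


def _cophenetic(tree, n):
    out = np.zeros((n, n))
    for node in tree.nodes():
        if node.is_leaf:
            continue
        left, right = node.children
        for i in left.leaves:
            for j in right.leaves:
                out[i, j] = out[j, i] = 2 * node.height
    return out


def test_upgma_ultrametric_fixed_point():
    """On an ultrametric input the tree reproduces the distances exactly."""
    d = np.array(
        [
            [0, 2, 8, 8],
            [2, 0, 8, 8],
            [8, 8, 0, 4],
            [8, 8, 4, 0],
        ],
        dtype=float,
    )
    tree = upgma(dm(d))
    assert np.allclose(_cophenetic(tree, 4), d)


def test_upgma_matches_scipy_average_linkage():
    """Cophenetic heights agree with scipy's average linkage (no ties)."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = int(rng.integers(4, 9))
        d = rng.uniform(1, 10, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = upgma(dm(d))
        z = linkage(squareform(d), method="average")
        expected = squareform(cophenet(z))
        assert np.allclose(_cophenetic(tree, n), expected)


def test_upgma_newick_is_parseable():
    import dendropy

    d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
    tree = upgma(dm(d, ids=("a", "b", "c")))
    parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {"a", "b", "c"}


# ---------------------------------------------------------------- quality


def test_cluster_quality_examples():
    d = np.array(
        [
            [0, 1, 5, 6],
            [1, 0, 5, 6],
            [5, 5, 0, 1],
            [6, 6, 1, 0],
        ],
        dtype=float,
    )
    assert cluster_quality([0, 1], d) == pytest.approx(4.0)  # min ext 5, diam 1
    assert cluster_quality([0], d) == pytest.approx(1.0)  # singleton: nn - 0
    # internal diameter above external minimum -> negative
    assert cluster_quality([0, 2], d) < 0
    assert cluster_quality([0, 1, 2, 3], d) == float("-inf")


# ---------------------------------------------------------------- DP oracle


def _enumerate_partitions(node):
    """All tree-consistent partitions of a subtree (as lists of leaf sets)."""
    own = [[node.leaves]]
    if node.is_leaf:
        return own
    left = _enumerate_partitions(node.children[0])
    right = _enumerate_partitions(node.children[1])
    return own + [l + r for l in left for r in right]


def _sorted_key(qualities):
    """Ascending quality vector, padded with +inf for lexicographic max."""
    return tuple(sorted(qualities))


def _lex_greater(a, b):
    """Lexicographic comparison treating missing tail entries as +inf."""
    for x, y in itertools.zip_longest(a, b, fillvalue=float("inf")):
        if x != y:
            return x > y
    return False


def test_dp_attains_lexicographic_maximum():
    """DP output equals brute-force lexmax over all tree-consistent cuts."""
    rng = np.random.default_rng(2024)
    for trial in range(120):
        n = int(rng.integers(3, 9))
        d = rng.uniform(0.5, 10, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dist = dm(d)
        tree = upgma(dist)
        result = best_tree_clustering(tree, dist)
        got = _sorted_key(result.qualities)
        best = None
        for partition in _enumerate_partitions(tree.root):
            qs = _sorted_key(cluster_quality(c, d) for c in partition)
            if best is None or _lex_greater(qs, best):
                best = qs
        assert got == pytest.approx(best), f"trial {trial}: {got} vs {best}"
        # partition covers all leaves disjointly
        leaves = sorted(i for c in result.clusters for i in c)
        assert leaves == list(range(n))


def test_dp_star_data_gives_singletons():
    # every off-diagonal distance equal: singleton nn-quality d beats any
    # larger cluster (min ext d - diam d = 0)
    d = np.full((5, 5), 3.0)
    np.fill_diagonal(d, 0)
    dist = dm(d)
    tree = upgma(dist)
    result = best_tree_clustering(tree, dist)
    assert sorted(len(c) for c in result.clusters) == [1, 1, 1, 1, 1]


def test_dp_two_clean_blocks():
    d = np.array(
        [
            [0, 0.1, 0.2, 5, 5, 5],
            [0.1, 0, 0.1, 5, 5, 5],
            [0.2, 0.1, 0, 5, 5, 5],
            [5, 5, 5, 0, 0.1, 0.2],
            [5, 5, 5, 0.1, 0, 0.1],
            [5, 5, 5, 0.2, 0.1, 0],
        ],
        dtype=float,
    )
    dist = dm(d)
    result = best_tree_clustering(upgma(dist), dist)
    assert sorted(tuple(c) for c in result.clusters) == [(0, 1, 2), (3, 4, 5)]


# ---------------------------------------------------------------- pipeline


def test_pipeline_deterministic_under_seed(concordant_family):
    aln = concordant_family.alignment
    r1 = run_sdpclust(aln, runs=20, seed=9)
    r2 = run_sdpclust(aln, runs=20, seed=9)
    assert r1.sdps.positions == r2.sdps.positions
    assert r1.grouping.labels == r2.grouping.labels
    assert np.array_equal(r1.distances.values, r2.distances.values)
    assert np.array_equal(r1.coassignment.counts, r2.coassignment.counts)


def test_coassignment_counts_invariants(concordant_family):
    aln = concordant_family.alignment
    from sdpclust import accumulate_coassignment

    cm = accumulate_coassignment(aln, runs=10, seed=3, restarts=1)
    assert np.array_equal(cm.counts, cm.counts.T)
    off = ~np.eye(aln.n_sequences, dtype=bool)
    assert cm.counts[off].max() <= cm.runs
    assert cm.counts[off].min() >= 0
    assert np.all(np.diag(cm.counts) == cm.runs)
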