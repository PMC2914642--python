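"""Iterative augmentation of specificity groups to a fixed point.

Starting from a (possibly small) training grouping, each iteration
scores SDPs on the current grouping, builds group PWMs over them, and
synchronously reassigns *every* sequence — training sequences included —
against those profiles.  Sequences without a confident winner fall into
the virtual group; groups emptied by reassignment are dropped, so the
number of groups never increases.  Iteration stops at a fixed point, on
a revisited grouping (cycle), or at the iteration cap.  On a cycle the
visited state with the most significant SDP set is returned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mi_moments import MomentTable, build_moment_table
from .msa_io import GAP_CODE, Alignment, GroupAssignment
from .sdp_profile import (
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_THETA_PER_COLUMN,
    _assign_all,
    _background_frequencies,
)
from .sdp_scoring import (
    DEFAULT_ALPHA,
    DEFAULT_MAX_GAP_FRACTION,
    SDPPrediction,
    _best_prefix,
    _log_prefix_probabilities,
    _score_arrays,
    alignment_onehot,
    empty_prediction,
    score_columns,
    select_sdps,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_ITER = 100
#: Margin (nats per scored column) a sequence must reach in the final
#: consolidation sweep to stay out of the virtual group; ~log(20), i.e.
#: a twentyfold per-column preference for the winning group.
DEFAULT_CONSOLIDATION_THETA = 3.0


@dataclass(frozen=True)
class RefineResult:
    """Outcome of group refinement."""

    grouping: GroupAssignment
    sdps: SDPPrediction
    status: str  # converged | cycle | max_iter | no_sdps | collapsed
    n_iterations: int


class RefineEngine:
    """Array-level refinement over one alignment.

    Precomputes the encoded alignment, its one-hot expansion, the
    background frequencies and the null-moment table once, so that the
    stochastic resampling wrapper can run thousands of refinements
    cheaply.  States are integer group indices per sequence (-1 =
    virtual).
    """

    def __init__(
        self,
        alignment: Alignment,
        table: Optional[MomentTable] = None,
        k_max: Optional[int] = None,
        alpha: float = DEFAULT_ALPHA,
        max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        theta_per_column: float = DEFAULT_THETA_PER_COLUMN,
        consolidation_theta: float = DEFAULT_CONSOLIDATION_THETA,
    ) -> None:
        self.alignment = alignment
        self.enc = alignment.encoded()
        self.onehot = alignment_onehot(self.enc)
        self.background = _background_frequencies(self.enc)
        self.log_background = np.log(self.background)
        n = alignment.n_sequences
        if table is None:
            table = build_moment_table(k_max=max(2, k_max or 8), c_max=n)
        self.table = table
        self.alpha = alpha
        self.log_alpha = math.log(alpha)
        self.max_gap_fraction = max_gap_fraction
        self.pseudocount = pseudocount
        self.theta_per_column = theta_per_column
        self.consolidation_theta = consolidation_theta
        self._mean_cache: dict = {}

    def _counts(self, gidx: np.ndarray, k: int) -> np.ndarray:
        membership = (gidx[None, :] == np.arange(k)[:, None]).astype(np.float32)
        n, _, length = self.onehot.shape
        counts = np.tensordot(
            membership, self.onehot.reshape(n, -1), axes=([1], [0])
        ).reshape(k, 20, length)
        return np.rint(counts).astype(np.int64)

    def score_and_select(
        self, gidx: np.ndarray, k: int
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Score all columns for a state; returns (counts, sdp_cols0, logP).

        ``sdp_cols0`` is empty when no significant set exists.
        """
        counts = self._counts(gidx, k)
        mi, mean, var, z, degenerate = _score_arrays(
            counts, self.table, mean_cache=self._mean_cache
        )
        assigned = gidx >= 0
        n_assigned = int(assigned.sum())
        gap_frac = (self.enc[assigned] == GAP_CODE).sum(axis=0) / max(n_assigned, 1)
        eligible = (~degenerate) & (gap_frac <= self.max_gap_fraction)
        if not eligible.any():
            return counts, np.empty(0, dtype=np.int64), 0.0
        cols = np.nonzero(eligible)[0]
        order = cols[np.lexsort((cols, -z[cols]))]
        z_sorted = z[order]
        n_positive = int((z_sorted > 0).sum())
        if n_positive == 0:
            return counts, np.empty(0, dtype=np.int64), 0.0
        order = order[:n_positive]
        log_probs = _log_prefix_probabilities(
            z_sorted[:n_positive], n_columns=cols.size
        )
        best_m = _best_prefix(log_probs)
        best_log_p = float(log_probs[best_m - 1])
        if best_log_p > self.log_alpha:
            return counts, np.empty(0, dtype=np.int64), best_log_p
        return counts, np.sort(order[:best_m]), best_log_p

    def _weights(self, counts: np.ndarray, cols0: np.ndarray) -> np.ndarray:
        sub = counts[:, :, cols0].transpose(0, 2, 1).astype(float)  # (k, m, 20)
        n_gc = sub.sum(axis=2, keepdims=True)
        return (
            np.log(sub + self.pseudocount * self.background[None, None, :])
            - np.log(n_gc + self.pseudocount)
            - self.log_background[None, None, :]
        )

    def refine(
        self, gidx0: np.ndarray, max_iter: int = DEFAULT_MAX_ITER
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, str, int]:
        """Refine an initial state to a fixed point.

        Returns ``(gidx, label_map, sdp_cols0, log_set_p, status,
        n_iterations)`` where ``label_map[j]`` is the index of group j
        in the *initial* state's group list.
        """
        state = np.asarray(gidx0, dtype=np.int64).copy()
        label_map = np.arange(int(state.max()) + 1, dtype=np.int64)
        seen: dict[bytes, int] = {state.tobytes(): 0}
        history: list[tuple[np.ndarray, np.ndarray]] = [(state, label_map)]
        log_ps: list[float] = []
        status = "max_iter"
        sdp_cols0 = np.empty(0, dtype=np.int64)
        log_p = 0.0
        it = 0
        for it in range(1, max_iter + 1):
            k = label_map.size
            counts, sdp_cols0, log_p = self.score_and_select(state, k)
            log_ps.append(log_p)
            if sdp_cols0.size == 0:
                status = "no_sdps"
                break
            weights = self._weights(counts, sdp_cols0)
            new = _assign_all(self.enc, sdp_cols0, weights, self.theta_per_column)
            present = np.unique(new[new >= 0])
            if present.size < 1:
                status = "collapsed"
                break
            if present.size == 1:
                # a single surviving group cannot be scored further, but
                # its membership is still the run's outcome
                state = np.where(new >= 0, 0, -1)
                label_map = label_map[present]
                sdp_cols0 = np.empty(0, dtype=np.int64)
                status = "collapsed"
                break
            if present.size < k:  # drop emptied groups, keep order
                remap = -np.ones(k, dtype=np.int64)
                remap[present] = np.arange(present.size)
                new = np.where(new >= 0, remap[np.maximum(new, 0)], -1)
                new_label_map = label_map[present]
            else:
                new_label_map = label_map
            if new_label_map.size == label_map.size and np.array_equal(new, state):
                status = "converged"
                break
            key = new.tobytes()
            if key in seen:
                status = "cycle"
                first = seen[key]
                cyc = range(first, len(history))
                best = min(cyc, key=lambda i: log_ps[i] if i < len(log_ps) else 0.0)
                state, label_map = history[best]
                _, sdp_cols0, log_p = self.score_and_select(state, label_map.size)
                break
            seen[key] = len(history)
            history.append((new, new_label_map))
            state, label_map = new, new_label_map
        if status == "max_iter":
            _, sdp_cols0, log_p = self.score_and_select(state, label_map.size)
        state, label_map = self._consolidate(state, label_map, sdp_cols0)
        return state, label_map, sdp_cols0, log_p, status, it

    def _consolidate(
        self, state: np.ndarray, label_map: np.ndarray, sdp_cols0: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """One decisive-margin sweep over the final state.

        Membership in the reported groups requires a PWM margin of
        ``consolidation_theta`` per scored column; sequences below it
        move to the virtual group and emptied groups are dropped.  This
        keeps only assignments backed by strongly discriminating SDP
        profiles — diffuse groupings held together by many weakly
        informative columns dissolve here.
        """
        if sdp_cols0.size == 0 or label_map.size == 0:
            return state, label_map
        k = label_map.size
        counts = self._counts(state, k)
        weights = self._weights(counts, sdp_cols0)
        new = _assign_all(self.enc, sdp_cols0, weights, self.consolidation_theta)
        present = np.unique(new[new >= 0])
        if present.size == 0:
            return np.full_like(state, -1), label_map[:0]
        remap = -np.ones(k, dtype=np.int64)
        remap[present] = np.arange(present.size)
        new = np.where(new >= 0, remap[np.maximum(new, 0)], -1)
        return new, label_map[present]


def refine_groups(
    alignment: Alignment,
    seed_grouping: GroupAssignment,
    table: Optional[MomentTable] = None,
    max_iter: int = DEFAULT_MAX_ITER,
    min_group_size: int = 2,
    **engine_params,
) -> RefineResult:
    """Refine a seed grouping until the assignment stops changing.

    The seed must provide at least two real groups of at least
    ``min_group_size`` sequences.  Returns the final grouping together
    with the SDP prediction made on it; if no significant SDP set exists
    for the seed, the seed is returned unchanged and flagged.
    """
    if seed_grouping.k < 2:
        raise ValueError("seed grouping needs at least 2 real groups")
    for lab, size in seed_grouping.sizes.items():
        if size < min_group_size:
            raise ValueError(
                f"seed group {lab!r} has {size} sequences (< {min_group_size})"
            )
    engine = RefineEngine(alignment, table=table, k_max=seed_grouping.k, **engine_params)
    gidx0 = seed_grouping.indices()
    gidx, label_map, sdp_cols0, _, status, n_iter = engine.refine(
        gidx0, max_iter=max_iter
    )
    seed_labels = seed_grouping.group_labels
    labels = tuple(
        seed_labels[label_map[g]] if g >= 0 else None for g in gidx
    )
    grouping = GroupAssignment(ids=alignment.ids, labels=labels)
    if status == "no_sdps" and n_iter == 1:
        logger.warning("no significant SDP set for the seed grouping; returned as-is")
        return RefineResult(
            grouping=seed_grouping,
            sdps=empty_prediction(),
            status="no_sdps",
            n_iterations=1,
        )
    if grouping.k >= 2:
        scores = score_columns(
            alignment,
            grouping,
            table=engine.table,
            max_gap_fraction=engine.max_gap_fraction,
        )
        sdps = select_sdps(scores, alpha=engine.alpha)
    else:
        sdps = empty_prediction()
    if status == "cycle":
        logger.info("refinement cycled after %d iterations", n_iter)
    return RefineResult(
        grouping=grouping, sdps=sdps, status=status, n_iterations=n_iter
    )
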