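"""Group profiles over SDP columns and sequence classification.

Each specificity group is summarised by a positional weight matrix
(PWM) of log-odds scores over the 20 amino acids, restricted to the
predicted SDP columns and ignoring the rest of the alignment.  A query
sequence is scored against every group PWM; it is assigned to the
best-scoring group only when that score is positive and beats the
runner-up by a margin theta, otherwise it falls into the virtual group.
The default margin is log 2 per scored SDP column, i.e. the winning
group must be at least twice as likely per informative position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .msa_io import _AA_INDEX, GAP, GAP_CODE, Alignment, GroupAssignment
from .sdp_scoring import SDPPrediction

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_THETA_PER_COLUMN = math.log(2.0)


@dataclass(frozen=True)
class GroupProfiles:
    """Per-group log-odds PWMs restricted to the SDP columns.

    ``weights[g, c, a]`` is the log-odds of amino acid ``a`` at the
    c-th SDP column for group ``g``; ``sdp_columns`` are 1-based.
    """

    group_labels: tuple[str, ...]
    sdp_columns: tuple[int, ...]
    weights: np.ndarray  # (k, n_sdp, 20)
    background: np.ndarray  # (20,)
    pseudocount: float
    theta_per_column: float


def _background_frequencies(enc: np.ndarray) -> np.ndarray:
    """Whole-alignment amino-acid frequencies with add-one smoothing."""
    residues = enc[enc != GAP_CODE]
    counts = np.bincount(residues.astype(np.int64), minlength=20).astype(float)
    return (counts + 1.0) / (counts.sum() + 20.0)


def _profile_weights(
    enc: np.ndarray,
    gidx: np.ndarray,
    k: int,
    cols0: np.ndarray,
    background: np.ndarray,
    pseudocount: float,
) -> np.ndarray:
    """Log-odds tensor (k, n_cols, 20) from encoded rows and group indices."""
    sub = enc[:, cols0]  # (N, m)
    weights = np.empty((k, cols0.size, 20))
    log_b = np.log(background)
    for g in range(k):
        rows = sub[gidx == g]
        counts = np.zeros((cols0.size, 20))
        for c in range(cols0.size):
            col = rows[:, c]
            col = col[col != GAP_CODE]
            if col.size:
                counts[c] = np.bincount(col.astype(np.int64), minlength=20)
        n_gc = counts.sum(axis=1, keepdims=True)
        weights[g] = (
            np.log(counts + pseudocount * background[None, :])
            - np.log(n_gc + pseudocount)
            - log_b[None, :]
        )
    return weights


def build_profiles(
    alignment: Alignment,
    grouping: GroupAssignment,
    sdps: SDPPrediction,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    theta_per_column: float = DEFAULT_THETA_PER_COLUMN,
) -> GroupProfiles:
    """Build one PWM per real group over the predicted SDP columns.

    Weights are ``log[(count + c * b_a) / (n_group + c)] - log b_a``
    with background-proportional pseudocounts of total mass ``c`` and
    background ``b_a`` estimated from the whole alignment; gapped cells
    are excluded from the counts.
    """
    if sdps.is_empty:
        raise ValueError("no SDPs to profile")
    labels = grouping.group_labels
    if not labels:
        raise ValueError("grouping has no real groups")
    for lab, size in grouping.sizes.items():
        if size == 0:
            raise ValueError(f"group {lab!r} is empty")
    enc = alignment.encoded()
    cols0 = np.array([p - 1 for p in sdps.positions], dtype=np.int64)
    background = _background_frequencies(enc)
    weights = _profile_weights(
        enc, grouping.indices(), len(labels), cols0, background, pseudocount
    )
    return GroupProfiles(
        group_labels=labels,
        sdp_columns=sdps.positions,
        weights=weights,
        background=background,
        pseudocount=pseudocount,
        theta_per_column=theta_per_column,
    )


def score_sequence(row: str, profiles: GroupProfiles) -> np.ndarray:
    """Per-group PWM score of an aligned row; gapped SDP cells score 0."""
    scores = np.zeros(len(profiles.group_labels))
    for c, pos in enumerate(profiles.sdp_columns):
        res = row[pos - 1].upper()
        if res == GAP:
            continue
        scores += profiles.weights[:, c, _AA_INDEX[res]]
    return scores


def assign_sequence(row: str, profiles: GroupProfiles) -> Optional[str]:
    """Assign an aligned sequence to a group, or the virtual group (None).

    The best group wins only if its score is positive and exceeds the
    runner-up by ``theta_per_column`` times the number of non-gap SDP
    cells actually scored; otherwise the sequence stays virtual.
    """
    n_scored = sum(1 for pos in profiles.sdp_columns if row[pos - 1].upper() != GAP)
    if n_scored == 0:
        return None
    scores = score_sequence(row, profiles)
    order = np.argsort(scores)[::-1]
    best = scores[order[0]]
    second = scores[order[1]] if scores.size > 1 else -np.inf
    theta = profiles.theta_per_column * n_scored
    if best > 0 and best - second >= theta:
        return profiles.group_labels[int(order[0])]
    return None


def _assign_all(
    enc: np.ndarray,
    cols0: np.ndarray,
    weights: np.ndarray,
    theta_per_column: float,
) -> np.ndarray:
    """Vectorised reassignment of every row; returns group index or -1."""
    sub = enc[:, cols0]  # (N, m)
    nongap = sub != GAP_CODE
    n_scored = nongap.sum(axis=1)
    safe = np.where(nongap, sub, 0).astype(np.int64)
    col_idx = np.arange(cols0.size)
    # scores[n, g] = sum over non-gap cells of weights[g, c, aa]
    per_cell = weights[:, col_idx[None, :], safe]  # (k, N, m)
    per_cell = np.where(nongap[None, :, :], per_cell, 0.0)
    scores = per_cell.sum(axis=2).T  # (N, k)
    k = weights.shape[0]
    best_g = np.argmax(scores, axis=1)  # lowest index among ties
    if k == 1:
        best = scores[:, 0]
        second = np.full_like(best, -np.inf)
    else:
        top2 = -np.partition(-scores, 1, axis=1)[:, :2]
        best = top2[:, 0]
        second = top2[:, 1]
    theta = theta_per_column * n_scored
    ok = (best > 0) & (best - second >= theta) & (n_scored > 0)
    return np.where(ok, best_g, -1)
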