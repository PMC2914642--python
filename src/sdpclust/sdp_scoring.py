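"""Column scoring and SDP selection (the fast scoring pass).

Each alignment column is scored by the mutual information between its
amino-acid distribution and the specificity grouping, computed in count
form

    MI_p = (1/N) * sum_{alpha, j} i_aj * log(i_aj * N / (i_a * n_j)),

where i_aj counts amino acid alpha in group j at the column, N is the
number of assigned, non-gapped residues there, and virtual-group
sequences and gaps are excluded.  MI becomes a Z-score against the
label-shuffling null — exact hypergeometric mean, tabulated
independent-multinomial variance — and the SDP set is the least
probable prefix of the Z-ranking: for a prefix of size m whose weakest
member has upper-tail normal probability p_m, the chance that m or more
of the C eligible columns reach that score by luck is a binomial tail,
evaluated in log space.  The reported prefix is the smallest
sufficiently deep local minimum of that curve (see ``_best_prefix``),
and must clear the significance ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .mi_moments import (
    MomentTable,
    build_moment_table,
    expected_mi_shuffle_term,
)
from .msa_io import GAP_CODE, Alignment, GroupAssignment

#: Columns with more than this fraction of gaps (among assigned
#: sequences) are not SDP candidates.
DEFAULT_MAX_GAP_FRACTION = 0.5
#: Largest null-set probability still reported as an SDP set.
DEFAULT_ALPHA = 0.05
_VAR_EPS = 1e-12


@dataclass(frozen=True)
class ColumnScore:
    """Score of one alignment column against a grouping."""

    position: int  # 1-based
    mi: float
    null_mean: float
    null_var: float
    z: float
    degenerate: bool
    gap_fraction: float
    eligible: bool


@dataclass(frozen=True)
class SDPPrediction:
    """A selected SDP set with its null probability and all scores."""

    positions: tuple[int, ...]  # 1-based, ascending
    set_probability: float
    log_set_probability: float
    scores: tuple[ColumnScore, ...]

    @property
    def is_empty(self) -> bool:
        return not self.positions


def empty_prediction(scores: Sequence[ColumnScore] = ()) -> SDPPrediction:
    return SDPPrediction(
        positions=(),
        set_probability=1.0,
        log_set_probability=0.0,
        scores=tuple(scores),
    )


def _group_count_tensor(enc: np.ndarray, gidx: np.ndarray, k: int) -> np.ndarray:
    """counts[j, a, l]: amino acid a of group j at column l (gaps dropped)."""
    n, length = enc.shape
    counts = np.zeros((k, 20, length), dtype=np.int64)
    for j in range(k):
        rows = enc[gidx == j]
        if rows.size == 0:
            continue
        for l in range(length):
            col = rows[:, l]
            col = col[col != GAP_CODE]
            if col.size:
                counts[j, :, l] += np.bincount(col, minlength=20)
    return counts


def alignment_onehot(enc: np.ndarray) -> np.ndarray:
    """(N, 20, L) float32 one-hot of an encoded alignment; gaps all-zero."""
    n, length = enc.shape
    onehot = np.zeros((n, 20, length), dtype=np.float32)
    idx_n, idx_l = np.nonzero(enc != GAP_CODE)
    onehot[idx_n, enc[idx_n, idx_l], idx_l] = 1.0
    return onehot


def _mi_from_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column MI and effective group numbers from counts[j, a, l].

    Columns with fewer than two non-empty groups get MI = 0.
    """
    group_sizes = counts.sum(axis=1)  # (k, L)
    totals = counts.sum(axis=0)  # (20, L)
    n_col = group_sizes.sum(axis=0)  # (L,)
    k_eff = (group_sizes > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = counts * n_col[None, None, :] / (
            totals[None, :, :] * group_sizes[:, None, :]
        )
        terms = np.where(counts > 0, counts * np.log(np.where(counts > 0, ratio, 1.0)), 0.0)
    mi = terms.sum(axis=(0, 1)) / np.maximum(n_col, 1)
    mi = np.where(k_eff >= 2, np.maximum(mi, 0.0), 0.0)
    return mi, k_eff


def _exact_null_means(
    counts: np.ndarray, cache: Optional[dict] = None
) -> np.ndarray:
    """Exact shuffle-null mean of MI per column from counts[j, a, l].

    Sums the closed-form hypergeometric expectation of every
    (amino acid, group) cell and divides by the column's assigned
    non-gap count.  Distinct (i_alpha, n_j, N) triples are memoised in
    ``cache`` so repeated scoring of one alignment is cheap.
    """
    if cache is None:
        cache = {}
    k, _, length = counts.shape
    totals = counts.sum(axis=0)  # (20, L)
    group_sizes = counts.sum(axis=1)  # (k, L)
    n_col = group_sizes.sum(axis=0)  # (L,)
    ia = np.broadcast_to(totals[None, :, :], counts.shape)
    nj = np.broadcast_to(group_sizes[:, None, :], counts.shape)
    nc = np.broadcast_to(n_col[None, None, :], counts.shape)
    valid = (ia > 0) & (nj > 0)
    base = int(n_col.max(initial=0)) + 1
    keys = (
        ia[valid].astype(np.int64) * base * base
        + nj[valid].astype(np.int64) * base
        + nc[valid].astype(np.int64)
    )
    uniq, inverse = np.unique(keys, return_inverse=True)
    term_values = np.empty(uniq.size)
    for idx, key in enumerate(uniq):
        i_alpha, rest = divmod(int(key), base * base)
        g_size, n_total = divmod(rest, base)
        triple = (i_alpha, g_size, n_total)
        if triple not in cache:
            cache[triple] = expected_mi_shuffle_term(*triple)
        term_values[idx] = cache[triple]
    cell_means = np.zeros(counts.shape)
    cell_means[valid] = term_values[inverse]
    return cell_means.sum(axis=(0, 1)) / np.maximum(n_col, 1)


def _score_arrays(
    counts: np.ndarray, table: MomentTable, mean_cache: Optional[dict] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(mi, mean, var, z, degenerate) per column from counts[j, a, l].

    The null mean is the exact label-shuffling expectation; the null
    variance is the tabulated independent-multinomial approximation,
    which sets the scale of the Z-scores.
    """
    mi, k_eff = _mi_from_counts(counts)
    totals = counts.sum(axis=0)  # (20, L)
    n_col = counts.sum(axis=(0, 1))  # (L,)
    length = counts.shape[2]
    mean = _exact_null_means(counts, cache=mean_cache)
    var = np.zeros(length)
    for k in np.unique(k_eff):
        if k < 2:
            continue
        cols = np.nonzero(k_eff == k)[0]
        _, v = table.lookup(totals[:, cols], int(k))
        var[cols] = v.sum(axis=0) / (n_col[cols] ** 2)
    mean = np.where(k_eff >= 2, mean, 0.0)
    # a column with fewer than two residue kinds is constant under label
    # shuffling and can never be an SDP
    n_distinct = (totals > 0).sum(axis=0)
    degenerate = (k_eff < 2) | (var <= _VAR_EPS) | (n_distinct < 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, (mi - mean) / np.sqrt(np.maximum(var, _VAR_EPS)))
    return mi, mean, var, z, degenerate


def column_mi(column: Sequence[str], grouping: GroupAssignment) -> float:
    """Mutual information of one column (residue per sequence) with a grouping.

    Virtual-group sequences and gaps are excluded; fewer than two
    non-empty groups at the column yields 0.
    """
    if len(column) != len(grouping.ids):
        raise ValueError("column length does not match grouping")
    if grouping.k < 2:
        raise ValueError("at least 2 real groups required")
    from .msa_io import _AA_INDEX, GAP

    gidx = grouping.indices()
    counts = np.zeros((grouping.k, 20), dtype=np.int64)
    for res, g in zip(column, gidx):
        if g < 0 or res == GAP:
            continue
        counts[g, _AA_INDEX[res.upper()]] += 1
    mi, k_eff = _mi_from_counts(counts[:, :, None])
    return float(mi[0])


def score_columns(
    alignment: Alignment,
    grouping: GroupAssignment,
    table: Optional[MomentTable] = None,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> list[ColumnScore]:
    """Score every column of the alignment against the grouping."""
    if grouping.k < 2:
        raise ValueError("at least 2 real groups required")
    if table is None:
        table = build_moment_table(
            k_max=max(2, grouping.k), c_max=alignment.n_sequences
        )
    enc = alignment.encoded()
    gidx = grouping.indices()
    counts = _group_count_tensor(enc, gidx, grouping.k)
    mi, mean, var, z, degenerate = _score_arrays(counts, table)
    assigned = gidx >= 0
    n_assigned = int(assigned.sum())
    gap_frac = (enc[assigned] == GAP_CODE).sum(axis=0) / max(n_assigned, 1)
    out = []
    for l in range(alignment.length):
        out.append(
            ColumnScore(
                position=l + 1,
                mi=float(mi[l]),
                null_mean=float(mean[l]),
                null_var=float(var[l]),
                z=float(z[l]),
                degenerate=bool(degenerate[l]),
                gap_fraction=float(gap_frac[l]),
                eligible=bool(
                    not degenerate[l] and gap_frac[l] <= max_gap_fraction
                ),
            )
        )
    return out


def _log_prefix_probabilities(z_sorted: np.ndarray, n_columns: int) -> np.ndarray:
    """log P(Binomial(C, p_m) >= m) for every prefix size m.

    ``p_m`` is the standard-normal upper-tail probability of the m-th
    largest Z-score.  Everything stays in log space so that extreme
    Z-scores still produce strictly ordered probabilities.
    """
    m_count = z_sorted.size
    log_p = norm.logsf(z_sorted)  # (m,)
    log_q = norm.logcdf(z_sorted)  # log(1 - p)
    j = np.arange(n_columns + 1, dtype=float)
    log_choose = (
        gammaln(n_columns + 1) - gammaln(j + 1) - gammaln(n_columns - j + 1)
    )
    terms = (
        log_choose[None, :]
        + j[None, :] * log_p[:, None]
        + (n_columns - j)[None, :] * log_q[:, None]
    )
    mask = j[None, :] < np.arange(1, m_count + 1, dtype=float)[:, None]
    terms = np.where(mask, -np.inf, terms)
    return np.minimum(logsumexp(terms, axis=1), 0.0)


#: A candidate prefix must reach this fraction of the global maximum
#: log-improbability to be preferred over larger prefixes.
DEFAULT_PREFIX_GAMMA = 0.5


def _best_prefix(log_probs: np.ndarray, gamma: float = DEFAULT_PREFIX_GAMMA) -> int:
    """Smallest sufficiently deep local minimum of the tail probability.

    The binomial tail of the m-th ranked Z-score keeps creeping lower as
    long as individually significant columns are appended, so its global
    minimum absorbs every moderately scoring column.  A sharp drop in
    the ranked Z-scores, however, produces a pronounced dip at the
    coherent block of extreme columns.  The rule returns the smallest
    local minimum whose log-probability reaches at least ``gamma``
    times the global minimum (both are negative), i.e. a compact block
    nearly as improbable as the best achievable set wins over a bloated
    one.
    """
    global_min = float(log_probs.min())
    threshold = gamma * global_min
    n = log_probs.size
    for m in range(n):
        left_ok = m == 0 or log_probs[m] <= log_probs[m - 1]
        right_ok = m == n - 1 or log_probs[m] <= log_probs[m + 1]
        if left_ok and right_ok and log_probs[m] <= threshold:
            return m + 1
    return int(np.argmin(log_probs)) + 1


def select_sdps(
    scores: Sequence[ColumnScore],
    alpha: float = DEFAULT_ALPHA,
) -> SDPPrediction:
    """Select the least probable high-Z prefix of columns as the SDP set.

    Eligible columns are ranked by Z (ties broken by lower column
    index); the prefix whose binomial tail probability is smallest is
    selected, smaller prefixes winning ties.  If even the best prefix is
    more probable than ``alpha`` under the null, the prediction is
    empty.
    """
    if not scores:
        raise ValueError("scores must be nonempty")
    eligible = [s for s in scores if s.eligible]
    if not eligible:
        return empty_prediction(scores)
    order = sorted(eligible, key=lambda s: (-s.z, s.position))
    z_sorted = np.array([s.z for s in order])
    # A column at or below its null mean can never belong to the least
    # probable set; prefixes are limited to strictly positive Z-scores.
    n_positive = int((z_sorted > 0).sum())
    if n_positive == 0:
        return empty_prediction(scores)
    log_probs = _log_prefix_probabilities(
        z_sorted[:n_positive], n_columns=len(eligible)
    )
    best_m = _best_prefix(log_probs)
    best_log_p = float(log_probs[best_m - 1])
    if best_log_p > math.log(alpha):
        return empty_prediction(scores)
    positions = tuple(sorted(s.position for s in order[:best_m]))
    return SDPPrediction(
        positions=positions,
        set_probability=float(np.exp(best_log_p)),
        log_set_probability=best_log_p,
        scores=tuple(scores),
    )
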