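"""Analytic null moments of per-column mutual information.

Scoring a column against a grouping requires the mean and variance of
its mutual information under a random model in which group labels carry
no information.  Instead of estimating these by shuffling, we compute
them analytically under the approximation that each amino acid's counts
are distributed independently over k equally sized groups, i.e. the
occupancy vector of an amino acid present i_alpha times is multinomial
with k equiprobable cells.  Under that model a single amino acid
contributes

    S = sum_j i_j * log(i_j * k / i_alpha)

to N * MI, and its mean and variance have closed binomial/trinomial
forms.  Both moments are pre-tabulated over (i_alpha, k) so that scoring
a column is a table lookup; a column's null mean is the sum of
single-amino-acid means divided by N, and its null variance the sum of
single variances divided by N**2 (cross-amino-acid covariances vanish
under the independence approximation).

All logarithms are natural.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

_CACHE_FORMAT_VERSION = 1
_VAR_CLIP_TOL = 1e-9


def _check_args(i_alpha: int, k: int) -> None:
    if int(i_alpha) != i_alpha or int(k) != k:
        raise ValueError("i_alpha and k must be integers")
    if i_alpha < 1 or k < 1:
        raise ValueError("i_alpha and k must be positive")


def expected_mi_single(i_alpha: int, k: int) -> float:
    """Mean of a single amino acid's MI contribution under the null.

    ``i_alpha`` occurrences are dropped independently into ``k``
    equiprobable groups; the statistic is the sum over groups of
    ``i * log(i * k / i_alpha)`` (terms with ``i = 0`` contribute 0).
    By group exchangeability the mean equals ``k`` times the binomial
    expectation of a single group's term.
    """
    _check_args(i_alpha, k)
    if k == 1:
        return 0.0
    i_alpha = int(i_alpha)
    k = int(k)
    i = np.arange(1, i_alpha + 1, dtype=float)
    log_w = (
        gammaln(i_alpha + 1)
        - gammaln(i + 1)
        - gammaln(i_alpha - i + 1)
        + i * np.log(1.0 / k)
        + (i_alpha - i) * np.log1p(-1.0 / k)
    )
    terms = np.exp(log_w) * i * np.log(i * k / i_alpha)
    return float(k * terms.sum())


def variance_mi_single(i_alpha: int, k: int) -> float:
    """Variance of a single amino acid's MI contribution under the null.

    Decomposes ``Var(S)`` into ``k`` identical squared terms plus
    ``k**2 - k`` identical cross terms between two distinct groups,
    whose joint occupancy is trinomial with cell probabilities
    ``(1/k, 1/k, 1 - 2/k)``.  The result is clipped at zero against
    floating-point cancellation.
    """
    _check_args(i_alpha, k)
    if k == 1:
        return 0.0
    i_alpha = int(i_alpha)
    k = int(k)
    i = np.arange(1, i_alpha + 1, dtype=float)
    g = i * np.log(i * k / i_alpha)
    log_binw = (
        gammaln(i_alpha + 1)
        - gammaln(i + 1)
        - gammaln(i_alpha - i + 1)
        + i * np.log(1.0 / k)
        + (i_alpha - i) * np.log1p(-1.0 / k)
    )
    square_term = k * float((np.exp(log_binw) * g * g).sum())

    # Cross term: pairs (i1 >= 1, i2 >= 1, i1 + i2 <= i_alpha).
    i1 = i[:, None]
    i2 = i[None, :]
    rest = i_alpha - i1 - i2
    valid = rest >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        # (1 - 2/k) ** rest with the 0 ** 0 == 1 convention (k == 2).
        log_rest = np.where(rest > 0, rest * np.log1p(-2.0 / k), 0.0)
        log_triw = (
            gammaln(i_alpha + 1)
            - gammaln(i1 + 1)
            - gammaln(i2 + 1)
            - gammaln(np.where(valid, rest, 0.0) + 1)
            + (i1 + i2) * np.log(1.0 / k)
            + log_rest
        )
        cross = np.where(valid, np.exp(log_triw) * g[:, None] * g[None, :], 0.0)
    cross_term = (k * k - k) * float(cross.sum())

    mean = expected_mi_single(i_alpha, k)
    var = square_term + cross_term - mean * mean
    if var < -_VAR_CLIP_TOL:
        logger.debug(
            "variance clipped from %.3e at (i_alpha=%d, k=%d)", var, i_alpha, k
        )
    return max(var, 0.0)


def expected_mi_shuffle_term(i_alpha: int, group_size: int, n_total: int) -> float:
    """Exact null mean of one group's MI term under label shuffling.

    When group labels are randomly permuted over the ``n_total``
    assigned sequences of a column, the count of an amino acid present
    ``i_alpha`` times inside a group of ``group_size`` is hypergeometric,
    and E[i * log(i * n_total / (i_alpha * group_size))] has a short
    closed form.  Summing over amino acids and groups (and dividing by
    ``n_total``) gives the exact expectation of the column MI under the
    shuffle null — no independence or equal-group-size approximation.
    """
    if i_alpha < 1 or group_size < 0 or n_total < 1:
        raise ValueError("arguments must be positive (group_size may be 0)")
    if group_size == 0 or i_alpha > n_total or group_size > n_total:
        raise ValueError("infeasible counts")
    lo = max(1, i_alpha + group_size - n_total)
    hi = min(i_alpha, group_size)
    if hi < lo:
        return 0.0
    i = np.arange(lo, hi + 1, dtype=float)
    log_pmf = (
        gammaln(i_alpha + 1)
        - gammaln(i + 1)
        - gammaln(i_alpha - i + 1)
        + gammaln(n_total - i_alpha + 1)
        - gammaln(group_size - i + 1)
        - gammaln(n_total - i_alpha - group_size + i + 1)
        - gammaln(n_total + 1)
        + gammaln(group_size + 1)
        + gammaln(n_total - group_size + 1)
    )
    terms = np.exp(log_pmf) * i * np.log(i * n_total / (i_alpha * group_size))
    return float(terms.sum())


@dataclass
class MomentTable:
    """Dense pre-tabulated null moments, with on-the-fly fallback.

    ``mean[c, k]`` and ``var[c, k]`` hold the moments for a count ``c``
    in 1..c_max and group number ``k`` in 2..k_max (other cells are 0 by
    convention: ``k = 1`` or ``c = 0`` carry no information).  Lookups
    outside the tabulated range are computed on demand, memoised and
    logged.
    """

    k_max: int
    c_max: int
    mean: np.ndarray
    var: np.ndarray
    _extra: dict = field(default_factory=dict, repr=False)
    _warned: bool = field(default=False, repr=False)

    def lookup(self, counts: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised moments for an array of amino-acid counts at one k."""
        counts = np.asarray(counts, dtype=np.int64)
        if k <= self.k_max and counts.max(initial=0) <= self.c_max:
            if k < 2:
                return np.zeros(counts.shape), np.zeros(counts.shape)
            return self.mean[counts, k], self.var[counts, k]
        return self._lookup_slow(counts, k)

    def _lookup_slow(self, counts: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        if not self._warned:
            logger.info(
                "moment lookup outside tabulated range (k=%d, max count=%d); "
                "computing on the fly",
                k,
                int(counts.max(initial=0)),
            )
            self._warned = True
        m = np.zeros(counts.shape)
        v = np.zeros(counts.shape)
        if k < 2:
            return m, v
        flat = counts.ravel()
        mf = m.ravel()
        vf = v.ravel()
        for idx, c in enumerate(flat):
            if c == 0:
                continue
            c = int(c)
            if c <= self.c_max and k <= self.k_max:
                mf[idx] = self.mean[c, k]
                vf[idx] = self.var[c, k]
                continue
            key = (c, k)
            if key not in self._extra:
                self._extra[key] = (
                    expected_mi_single(c, k),
                    variance_mi_single(c, k),
                )
            mf[idx], vf[idx] = self._extra[key]
        return m, v

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            str(path),
            format_version=np.int64(_CACHE_FORMAT_VERSION),
            k_max=np.int64(self.k_max),
            c_max=np.int64(self.c_max),
            mean=self.mean,
            var=self.var,
        )

    @classmethod
    def load(cls, path: str | Path) -> "MomentTable":
        with np.load(str(path)) as npz:
            if int(npz["format_version"]) != _CACHE_FORMAT_VERSION:
                raise ValueError("moment-table cache has an unsupported version")
            return cls(
                k_max=int(npz["k_max"]),
                c_max=int(npz["c_max"]),
                mean=npz["mean"],
                var=npz["var"],
            )


def build_moment_table(
    k_max: int = 200,
    c_max: int = 500,
    cache_path: Optional[str | Path] = None,
) -> MomentTable:
    """Tabulate both moments for k = 2..k_max and counts 1..c_max.

    The build is deterministic; if ``cache_path`` names an existing
    cache with matching dimensions it is loaded instead, otherwise the
    table is built and written there.  The full default table
    (k_max=200, c_max=500) is a one-off costing a few minutes; callers
    scoring a specific alignment only need ``k_max`` of the order of
    the number of groups and ``c_max = N``.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if c_max < 1:
        raise ValueError("c_max must be >= 1")
    if cache_path is not None and Path(cache_path).exists():
        try:
            table = MomentTable.load(cache_path)
            if table.k_max == k_max and table.c_max == c_max:
                return table
        except (ValueError, KeyError, OSError):
            logger.warning("ignoring unreadable moment cache %s", cache_path)
    mean = np.zeros((c_max + 1, k_max + 1))
    var = np.zeros((c_max + 1, k_max + 1))
    for c in range(1, c_max + 1):
        for k in range(2, k_max + 1):
            mean[c, k] = expected_mi_single(c, k)
            var[c, k] = variance_mi_single(c, k)
    table = MomentTable(k_max=k_max, c_max=c_max, mean=mean, var=var)
    if cache_path is not None:
        table.save(cache_path)
    return table


@dataclass(frozen=True)
class ColumnCounts:
    """Per-group amino-acid counts at one alignment column.

    ``counts[j, a]`` is the number of sequences of group ``j`` carrying
    amino acid ``a`` at the column; gapped and virtual-group cells are
    excluded.
    """

    counts: np.ndarray  # (k, 20) int

    @property
    def totals(self) -> np.ndarray:
        """Count of each amino acid over all groups (i_alpha)."""
        return self.counts.sum(axis=0)

    @property
    def group_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n(self) -> int:
        """Number of counted (assigned, non-gap) residues."""
        return int(self.counts.sum())

    @property
    def k_effective(self) -> int:
        """Number of groups with at least one counted residue."""
        return int((self.group_sizes > 0).sum())


def column_null_moments(
    counts: ColumnCounts, table: MomentTable
) -> tuple[float, float]:
    """Null mean and variance of a column's MI given its counts.

    mean = sum_alpha M(i_alpha, k) / N and var = sum_alpha D(i_alpha, k)
    / N**2, with k the number of non-empty groups at the column and N
    the counted residues.  Empty columns yield (0, 0).
    """
    n = counts.n
    if n == 0:
        return 0.0, 0.0
    k = counts.k_effective
    totals = counts.totals
    m, v = table.lookup(totals, k)
    return float(m.sum() / n), float(v.sum() / (n * n))
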