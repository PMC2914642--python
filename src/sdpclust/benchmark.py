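"""Evaluation metrics for SDP predictions and specificity groupings.

Covers position-level sensitivity / false-positive rate against a gold
SDP set, the normalised mutual-information distance between two
sequence partitions, a one-sided Mann-Whitney test of whether predicted
SDPs sit closer to the ligand than residues in general, and the
structure-derived gold-standard rule (true SDPs are residues within
10 A of the ligand; atomic contacts use a 5 A cutoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .msa_io import GroupAssignment, InputError

logger = logging.getLogger(__name__)

#: Residues closer than this to the ligand count as true SDPs.
TRUE_SDP_CUTOFF = 10.0
#: Two atoms closer than this are considered in contact.
CONTACT_CUTOFF = 5.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(
    predicted: Iterable[int], gold: Iterable[int], universe: int
) -> ConfusionCounts:
    if universe <= 0:
        raise ValueError("universe must be positive")
    pred = set(predicted)
    pos = set(gold)
    all_pos = set(range(1, universe + 1))
    if not pred <= all_pos or not pos <= all_pos:
        raise ValueError("positions outside 1..universe")
    tp = len(pred & pos)
    fp = len(pred - pos)
    fn = len(pos - pred)
    tn = universe - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity_fpr(
    predicted: Iterable[int], gold: Iterable[int], universe: int
) -> tuple[float, float]:
    """TP/(TP+FN) and FP/(FP+TN) over 1-based alignment positions.

    An empty gold set makes sensitivity undefined (NaN).
    """
    cc = confusion_counts(predicted, gold, universe)
    sens = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) > 0 else float("nan")
    fpr = cc.fp / (cc.fp + cc.tn) if (cc.fp + cc.tn) > 0 else float("nan")
    return sens, fpr


@dataclass(frozen=True)
class GroupingComparison:
    """Contingency summary of two partitions of the same sequences."""

    joint: np.ndarray  # p_ij
    h_gold: float
    h_pred: float
    h_joint: float
    mi: float
    distance: float


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def compare_groupings(
    gold: GroupAssignment,
    predicted: GroupAssignment,
    restrict_to_gold: bool = True,
) -> GroupingComparison:
    """Joint distribution and MI-based distance of two groupings.

    Sequences are matched by id.  By default only sequences with a real
    (non-virtual) gold label are evaluated; virtual predicted labels are
    treated as one extra predicted group.  The distance is

        D = 1 - MI / H(joint),

    0 for identical partitions up to relabelling and 1 for independent
    ones; the log base cancels.
    """
    pred_label = dict(zip(predicted.ids, predicted.labels))
    pairs = []
    for sid, glab in zip(gold.ids, gold.labels):
        if glab is None and restrict_to_gold:
            continue
        if sid not in pred_label:
            raise InputError(f"sequence {sid!r} missing from predicted grouping")
        pairs.append((glab, pred_label[sid]))
    if len(pairs) < 2:
        raise ValueError("need at least 2 evaluated sequences")
    gold_labels = sorted({g for g, _ in pairs}, key=str)
    pred_labels = sorted({p for _, p in pairs}, key=str)
    gi = {lab: i for i, lab in enumerate(gold_labels)}
    pi = {lab: i for i, lab in enumerate(pred_labels)}
    table = np.zeros((len(gold_labels), len(pred_labels)))
    for g, p in pairs:
        table[gi[g], pi[p]] += 1
    joint = table / table.sum()
    h_gold = _entropy(joint.sum(axis=1))
    h_pred = _entropy(joint.sum(axis=0))
    h_joint = _entropy(joint.ravel())
    mi = h_gold + h_pred - h_joint
    if h_joint == 0.0:
        distance = 0.0  # both partitions constant, hence identical
    else:
        distance = 1.0 - mi / h_joint
    distance = min(max(distance, 0.0), 1.0)
    return GroupingComparison(
        joint=joint,
        h_gold=h_gold,
        h_pred=h_pred,
        h_joint=h_joint,
        mi=mi,
        distance=distance,
    )


def grouping_distance(
    gold: GroupAssignment, predicted: GroupAssignment, restrict_to_gold: bool = True
) -> float:
    """Normalised MI distance in [0, 1] between two groupings."""
    return compare_groupings(gold, predicted, restrict_to_gold).distance


def mannwhitney_sdp_distance(
    sdp_distances: Sequence[float], all_distances: Sequence[float]
) -> float:
    """One-sided Mann-Whitney p-value that SDPs lie closer to the ligand.

    Tests the alternative that SDP-to-ligand distances are
    stochastically smaller than the reference distances.  Exact
    enumeration is used for small tie-free samples, otherwise the
    normal approximation with continuity and tie correction.  Two
    identical constant samples are fully degenerate and yield p = 1.
    """
    x = np.asarray(sdp_distances, dtype=float)
    y = np.asarray(all_distances, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="less", method=method)
    return float(res.pvalue)


def true_sdps_from_structure(
    distances: Mapping[int, float], cutoff: float = TRUE_SDP_CUTOFF
) -> set[int]:
    """Alignment positions whose residue lies strictly closer than ``cutoff``.

    ``distances`` maps 1-based alignment positions to minimum
    heavy-atom distances to the ligand (Angstrom); unmapped positions
    are simply absent.
    """
    return {pos for pos, d in distances.items() if d < cutoff}


def contacting_positions(
    distances: Mapping[int, float], cutoff: float = CONTACT_CUTOFF
) -> set[int]:
    """Positions in atomic contact with the ligand (< 5 A by default)."""
    return true_sdps_from_structure(distances, cutoff=cutoff)


def read_distance_table(path: str | Path) -> dict[int, float]:
    """Read a position<TAB>distance_A table (1-based positions)."""
    out: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("position"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 2 fields")
            out[int(parts[0])] = float(parts[1])
    return out
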