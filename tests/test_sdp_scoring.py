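"""Column MI, Z-scores and SDP selection."""

import math

import numpy as np
import pytest

from sdpclust import (
    Alignment,
    GroupAssignment,
    column_mi,
    score_columns,
    select_sdps,
)
from sdpclust.sdp_scoring import ColumnScore, empty_prediction


def mi_from_frequencies(column, grouping):
    """Independent oracle: the frequency (Eq.-1 style) form of column MI."""
    pairs = [
        (res, lab)
        for res, lab in zip(column, grouping.labels)
        if lab is not None and res != "-"
    ]
    n = len(pairs)
    if n == 0:
        return 0.0
    residues = sorted({r for r, _ in pairs})
    labels = sorted({l for _, l in pairs})
    if len(labels) < 2:
        return 0.0
    mi = 0.0
    for r in residues:
        f_r = sum(1 for rr, _ in pairs if rr == r) / n
        for l in labels:
            f_l = sum(1 for _, ll in pairs if ll == l) / n
            f_rl = sum(1 for rr, ll in pairs if rr == r and ll == l) / n
            if f_rl > 0:
                mi += f_rl * math.log(f_rl / (f_r * f_l))
    return mi


def test_perfectly_split_column_is_log2(toy_alignment, toy_grouping):
    column = toy_alignment.column(10)  # AAAAA CCCCC
    assert column_mi(column, toy_grouping) == pytest.approx(math.log(2), abs=1e-12)


def test_constant_column_is_zero(toy_alignment, toy_grouping):
    assert column_mi(toy_alignment.column(1), toy_grouping) == pytest.approx(0.0)


def test_count_form_equals_frequency_form_on_random_columns():
    """Both MI formulations agree to 1e-12 on 1000 random columns."""
    rng = np.random.default_rng(77)
    aas = "ACDEFGHIKLMNPQRSTVWY-"
    for _ in range(1000):
        n = int(rng.integers(6, 25))
        k = int(rng.integers(2, 5))
        column = [aas[i] for i in rng.integers(0, 21, size=n)]
        labels = tuple(
            None if rng.random() < 0.2 else f"g{rng.integers(k)}" for _ in range(n)
        )
        grouping = GroupAssignment(ids=tuple(f"s{i}" for i in range(n)), labels=labels)
        if grouping.k < 2:
            continue
        got = column_mi(column, grouping)
        want = mi_from_frequencies(column, grouping)
        assert got == pytest.approx(want, abs=1e-12)


def test_mi_invariant_under_relabel_and_reorder():
    column = list("AACCGGKK")
    ids = tuple(f"s{i}" for i in range(8))
    g1 = GroupAssignment(ids=ids, labels=("x",) * 4 + ("y",) * 4)
    g2 = GroupAssignment(ids=ids, labels=("banana",) * 4 + ("apple",) * 4)
    assert column_mi(column, g1) == pytest.approx(column_mi(column, g2))
    perm = np.random.default_rng(1).permutation(8)
    g3 = GroupAssignment(
        ids=tuple(ids[i] for i in perm), labels=tuple(g1.labels[i] for i in perm)
    )
    assert column_mi([column[i] for i in perm], g3) == pytest.approx(
        column_mi(column, g1)
    )


def test_identical_sequences_all_degenerate(small_table):
    rows = ("ACDEF",) * 6
    aln = Alignment(ids=tuple(f"s{i}" for i in range(6)), rows=rows)
    grouping = GroupAssignment(ids=aln.ids, labels=("a",) * 3 + ("b",) * 3)
    scores = score_columns(aln, grouping, table=small_table)
    assert all(s.degenerate and s.z == 0.0 for s in scores)
    assert select_sdps(scores).is_empty


def test_virtual_sequences_do_not_affect_scores(toy_alignment, toy_grouping, small_table):
    base = score_columns(toy_alignment, toy_grouping, table=small_table)
    bigger = Alignment(
        ids=toy_alignment.ids + ("extra",),
        rows=toy_alignment.rows + ("WWWWWWWWWW",),
    )
    grouping = GroupAssignment(
        ids=bigger.ids, labels=toy_grouping.labels + (None,)
    )
    augmented = score_columns(bigger, grouping, table=small_table)
    for a, b in zip(base, augmented):
        assert a.mi == pytest.approx(b.mi)
        assert a.z == pytest.approx(b.z)


def test_implanted_columns_dominate_z(concordant_family, small_table):
    fam = concordant_family
    scores = score_columns(fam.alignment, fam.gold_grouping, table=small_table)
    implanted = [s.z for s in scores if s.position in fam.gold_sdps]
    others = [s.z for s in scores if s.position not in fam.gold_sdps]
    assert min(implanted) > max(others)


def test_selection_is_prefix_of_z_ranking(concordant_family, small_table):
    fam = concordant_family
    scores = score_columns(fam.alignment, fam.gold_grouping, table=small_table)
    pred = select_sdps(scores)
    assert not pred.is_empty
    ranked = sorted(
        (s for s in scores if s.eligible), key=lambda s: (-s.z, s.position)
    )
    prefix = {s.position for s in ranked[: len(pred.positions)]}
    assert set(pred.positions) == prefix


def test_gold_grouping_selects_exactly_the_implanted_block(
    concordant_family, small_table
):
    fam = concordant_family
    scores = score_columns(fam.alignment, fam.gold_grouping, table=small_table)
    pred = select_sdps(scores)
    assert pred.positions == fam.gold_sdps
    assert pred.log_set_probability < math.log(0.05)


def make_score(pos, z, eligible=True):
    return ColumnScore(
        position=pos,
        mi=0.0,
        null_mean=0.0,
        null_var=1.0,
        z=z,
        degenerate=not eligible,
        gap_fraction=0.0,
        eligible=eligible,
    )


def test_selection_stops_at_the_cliff():
    # three extreme columns, two near-null ones
    scores = [make_score(i + 1, z) for i, z in enumerate([10.0, 9.0, 8.0, 0.1, 0.0])]
    pred = select_sdps(scores)
    assert pred.positions == (1, 2, 3)


def test_selection_ignores_negative_z():
    scores = [make_score(i + 1, z) for i, z in enumerate([-1.0, -2.0, -0.5])]
    assert select_sdps(scores).is_empty


def test_selection_requires_significance():
    scores = [make_score(i + 1, z) for i, z in enumerate([1.0, 0.5, 0.2])]
    assert select_sdps(scores).is_empty


def test_selection_empty_input_raises():
    with pytest.raises(ValueError):
        select_sdps([])
    assert empty_prediction().is_empty


def test_scores_center_near_zero_under_label_permutation(small_table):
    """With the exact shuffle-null mean, permuted-label z-scores average ~0."""
    rng = np.random.default_rng(5)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    rows = tuple(
        "".join(aas[i] for i in rng.integers(0, 20, size=40)) for _ in range(24)
    )
    aln = Alignment(ids=tuple(f"s{i}" for i in range(24)), rows=rows)
    zs = []
    for _ in range(40):
        labels = tuple(f"g{j}" for j in rng.permutation(np.repeat(np.arange(3), 8)))
        grouping = GroupAssignment(ids=aln.ids, labels=labels)
        for s in score_columns(aln, grouping, table=small_table):
            if not s.degenerate:
                zs.append(s.z)
    zs = np.asarray(zs)
    # mean of (mi - exact mean)/approx sd: centred, though not unit scale
    assert abs(zs.mean()) < 0.1
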