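"""Synthetic protein families with implanted SDPs.

A naive random evolutionary model: a 190-residue root sequence is drawn
from SwissProt amino-acid frequencies; five subfamily seeds are derived
from it by 30 random point mutations each, and ten leaves per seed by a
further 50 mutations.  Specificity is implanted by appending ten extra
columns in which every specificity class carries its own fixed residue
(residues distinct across classes within a column), so the gold SDP set
and gold grouping are known by construction.  Specificity classes
either coincide with the subfamilies ("concordant") or are scattered
over them by a balanced random permutation ("random"), decoupling
specificity from phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .msa_io import AMINO_ACIDS, Alignment, GroupAssignment

# Amino-acid composition of UniProtKB/Swiss-Prot (release-statistics
# averages, percent); any fixed realistic table serves, as downstream
# results depend only weakly on the background composition.
SWISSPROT_FREQUENCIES: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}


def swissprot_probabilities() -> np.ndarray:
    """Normalised background probabilities in canonical alphabet order."""
    p = np.array([SWISSPROT_FREQUENCIES[aa] for aa in AMINO_ACIDS])
    return p / p.sum()


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one generated family."""

    root_length: int = 190
    n_subfamilies: int = 5
    seqs_per_subfamily: int = 10
    seed_mutations: int = 30
    leaf_mutations: int = 50
    n_sdps: int = 10
    pattern: Literal["concordant", "random"] = "concordant"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "root_length",
            "n_subfamilies",
            "seqs_per_subfamily",
            "n_sdps",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.seed_mutations < 0 or self.leaf_mutations < 0:
            raise ValueError("mutation counts must be nonnegative")
        if self.pattern not in ("concordant", "random"):
            raise ValueError("pattern must be 'concordant' or 'random'")


@dataclass(frozen=True)
class SyntheticFamily:
    """A generated family with its gold standard."""

    alignment: Alignment
    gold_grouping: GroupAssignment  # specificity classes
    gold_sdps: tuple[int, ...]  # 1-based implanted columns
    subfamilies: GroupAssignment  # phylogenetic subfamily labels
    spec: FamilySpec


def random_root(length: int, rng: np.random.Generator) -> str:
    """An i.i.d. random sequence drawn from SwissProt frequencies."""
    if length < 1:
        raise ValueError("length must be >= 1")
    codes = rng.choice(20, size=length, p=swissprot_probabilities())
    return "".join(AMINO_ACIDS[c] for c in codes)


def mutate(sequence: str, steps: int, rng: np.random.Generator) -> str:
    """Apply ``steps`` random point mutations.

    Each step picks a uniform position and replaces its residue with a
    uniform draw from the 19 other amino acids; positions may repeat, so
    ``steps`` is an upper bound on the Hamming distance to the input.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    seq = list(sequence)
    length = len(seq)
    for _ in range(steps):
        pos = int(rng.integers(length))
        old = seq[pos]
        choices = [aa for aa in AMINO_ACIDS if aa != old]
        seq[pos] = choices[int(rng.integers(19))]
    return "".join(seq)


def generate_family(spec: FamilySpec) -> SyntheticFamily:
    """Generate one family with implanted SDP columns and gold labels."""
    if spec.n_subfamilies > 20:
        raise ValueError(
            "cannot implant distinct class residues for more than 20 classes"
        )
    rng = np.random.default_rng(spec.seed)
    root = random_root(spec.root_length, rng)
    seeds = [
        mutate(root, spec.seed_mutations, rng) for _ in range(spec.n_subfamilies)
    ]
    rows: list[str] = []
    subfam: list[int] = []
    for j, seed_seq in enumerate(seeds):
        for _ in range(spec.seqs_per_subfamily):
            rows.append(mutate(seed_seq, spec.leaf_mutations, rng))
            subfam.append(j)
    n = len(rows)

    if spec.pattern == "concordant":
        classes = list(subfam)
    else:
        # balanced uniform scattering of classes over sequences
        perm = rng.permutation(n)
        classes = [0] * n
        for rank, i in enumerate(perm):
            classes[i] = rank // spec.seqs_per_subfamily

    n_classes = spec.n_subfamilies
    sdp_columns: list[list[str]] = []
    for _ in range(spec.n_sdps):
        residues = rng.choice(20, size=n_classes, replace=False)
        sdp_columns.append([AMINO_ACIDS[r] for r in residues])
    rows = [
        row + "".join(col[classes[i]] for col in sdp_columns)
        for i, row in enumerate(rows)
    ]

    ids = tuple(
        f"sf{j + 1}_{i + 1}"
        for j in range(spec.n_subfamilies)
        for i in range(spec.seqs_per_subfamily)
    )
    alignment = Alignment(ids=ids, rows=tuple(rows))
    gold = GroupAssignment(
        ids=ids, labels=tuple(f"class{c + 1}" for c in classes)
    )
    subfam_ga = GroupAssignment(
        ids=ids, labels=tuple(f"subfam{j + 1}" for j in subfam)
    )
    gold_sdps = tuple(
        range(spec.root_length + 1, spec.root_length + spec.n_sdps + 1)
    )
    return SyntheticFamily(
        alignment=alignment,
        gold_grouping=gold,
        gold_sdps=gold_sdps,
        subfamilies=subfam_ga,
        spec=spec,
    )
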