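"""Alignment and grouping containers plus file I/O.

Alignments are read from aligned FASTA; group assignments from a minimal
two-column TSV (sequence id, group label).  Trees are written as Newick,
distance matrices in the square PHYLIP dialect.  All residues are
normalised to the 20-letter amino-acid alphabet plus the gap character
``-``; ambiguous codes (B, Z, X, J, U, O) and ``*``/``.`` are mapped to
gap by default because every downstream statistic is defined over the 20
standard amino acids only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical amino-acid order used for all count matrices.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Integer code of the gap state in encoded alignments.
GAP_CODE = len(AMINO_ACIDS)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AMBIGUOUS = set("BZXJUO*.")

#: Reserved label for sequences without a confident group assignment.
VIRTUAL_LABEL = "__virtual__"


class AlignmentError(ValueError):
    """Raised when sequences do not form a valid alignment."""


class InputError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of protein sequences.

    Attributes
    ----------
    ids:
        Ordered, unique sequence identifiers.
    rows:
        One string per sequence, all of identical length, over the 20
        amino acids plus ``-``.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment must contain at least one sequence")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal lengths: {sorted(lengths)}")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("duplicate sequence ids")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in number")
        allowed = set(AMINO_ACIDS) | {GAP}
        for sid, row in zip(self.ids, self.rows):
            bad = set(row) - allowed
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains unexpected characters {sorted(bad)}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def encoded(self) -> np.ndarray:
        """Integer matrix (N x L); amino acids 0..19, gap ``GAP_CODE``."""
        enc = np.empty((self.n_sequences, self.length), dtype=np.int8)
        lut = np.full(128, -1, dtype=np.int8)
        for aa, i in _AA_INDEX.items():
            lut[ord(aa)] = i
        lut[ord(GAP)] = GAP_CODE
        for r, row in enumerate(self.rows):
            enc[r] = lut[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
        return enc

    def column(self, position: int) -> tuple[str, ...]:
        """Residues of a 1-based alignment column, in sequence order."""
        if not 1 <= position <= self.length:
            raise IndexError(f"column {position} outside 1..{self.length}")
        j = position - 1
        return tuple(row[j] for row in self.rows)


@dataclass(frozen=True)
class GroupAssignment:
    """Partial partition of sequence ids into labelled specificity groups.

    Sequences with label ``None`` belong to the virtual group: they are
    ignored when scoring SDPs but may be claimed by a group later.
    """

    ids: tuple[str, ...]
    labels: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.labels):
            raise InputError("ids and labels differ in number")
        if VIRTUAL_LABEL in self.labels:
            raise InputError(f"label {VIRTUAL_LABEL!r} is reserved")

    @classmethod
    def from_mapping(
        cls, alignment: Alignment, mapping: Mapping[str, str]
    ) -> "GroupAssignment":
        unknown = set(mapping) - set(alignment.ids)
        if unknown:
            raise InputError(f"ids not in alignment: {sorted(unknown)}")
        labels = tuple(mapping.get(sid) for sid in alignment.ids)
        ga = cls(ids=alignment.ids, labels=labels)
        if ga.k == 0:
            raise InputError("no real groups in mapping")
        return ga

    @property
    def group_labels(self) -> tuple[str, ...]:
        """Distinct real labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            if lab is not None and lab not in seen:
                seen[lab] = None
        return tuple(seen)

    @property
    def k(self) -> int:
        """Number of real (non-virtual) groups."""
        return len(self.group_labels)

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            if lab is not None:
                out[lab] = out.get(lab, 0) + 1
        return out

    @property
    def fractions(self) -> dict[str, float]:
        """n_j / (number of assigned sequences), summing to 1 over groups."""
        sizes = self.sizes
        total = sum(sizes.values())
        return {lab: n / total for lab, n in sizes.items()}

    def groups(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {lab: [] for lab in self.group_labels}
        for sid, lab in zip(self.ids, self.labels):
            if lab is not None:
                out[lab].append(sid)
        return {lab: tuple(v) for lab, v in out.items()}

    def label_of(self, sid: str) -> Optional[str]:
        return self.labels[self.ids.index(sid)]

    def indices(self) -> np.ndarray:
        """Integer group index per sequence; -1 for the virtual group."""
        order = {lab: i for i, lab in enumerate(self.group_labels)}
        return np.array(
            [-1 if lab is None else order[lab] for lab in self.labels], dtype=np.int64
        )


def _normalise(seq: str, ambiguous: str) -> str:
    out = []
    for ch in seq.upper():
        if ch in _AA_INDEX or ch == GAP:
            out.append(ch)
        elif ch in _AMBIGUOUS:
            if ambiguous == "gap":
                out.append(GAP)
            else:
                raise AlignmentError(f"ambiguous residue {ch!r} not allowed")
        else:
            raise AlignmentError(f"unknown residue code {ch!r}")
    return "".join(out)


def read_alignment(path: str | Path, ambiguous: str = "gap") -> Alignment:
    """Read an aligned FASTA file.

    Parameters
    ----------
    path:
        FASTA file of pre-aligned sequences.
    ambiguous:
        Policy for non-standard residue codes: ``"gap"`` (default) maps
        them to the gap state, ``"error"`` rejects the file.

    Raises
    ------
    InputError
        Empty file or duplicate ids.
    AlignmentError
        Ragged rows or disallowed characters.
    """
    if ambiguous not in {"gap", "error"}:
        raise ValueError("ambiguous policy must be 'gap' or 'error'")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no sequences found in {path}")
    ids = tuple(rec.id for rec in records)
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sequence ids in FASTA")
    rows = tuple(_normalise(str(rec.seq), ambiguous) for rec in records)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal lengths: {sorted(lengths)}")
    aln = Alignment(ids=ids, rows=rows)
    if aln.n_sequences < 4:
        logger.warning("alignment has only %d sequences (< 4)", aln.n_sequences)
    if aln.n_sequences > 2000:
        logger.warning("alignment has %d sequences (> 2000)", aln.n_sequences)
    if aln.length >= 5000:
        logger.warning("alignment length %d >= 5000", aln.length)
    return aln


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(alignment.ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_groups(path: str | Path, alignment: Alignment) -> GroupAssignment:
    """Read a two-column TSV of sequence id and group label.

    Sequences absent from the file are assigned to the virtual group.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sid, label = parts
            if sid in mapping:
                raise InputError(f"{path}:{lineno}: duplicate id {sid!r}")
            mapping[sid] = label
    return GroupAssignment.from_mapping(alignment, mapping)


def write_groups(grouping: GroupAssignment, path: str | Path) -> None:
    """Write assigned (non-virtual) sequences as id<TAB>label lines."""
    with open(path, "w") as fh:
        for sid, lab in zip(grouping.ids, grouping.labels):
            if lab is not None:
                fh.write(f"{sid}\t{lab}\n")


def write_sdp_list(sdps, path: str | Path) -> None:
    """Write selected SDP columns (1-based) with their Z-scores."""
    by_pos = {s.position: s for s in sdps.scores}
    with open(path, "w") as fh:
        fh.write("position\tz_score\n")
        for pos in sdps.positions:
            z = by_pos[pos].z if pos in by_pos else float("nan")
            fh.write(f"{pos}\t{z:.6f}\n")


def write_distance_matrix(ids: Sequence[str], d: np.ndarray, path: str | Path) -> None:
    """Write a square PHYLIP distance matrix (full precision)."""
    n = len(ids)
    if d.shape != (n, n):
        raise InputError("distance matrix shape does not match ids")
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i, sid in enumerate(ids):
            row = " ".join(format(x, ".12g") for x in d[i])
            fh.write(f"{sid}  {row}\n")


def read_distance_matrix(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    with open(path) as fh:
        header = fh.readline()
        n = int(header.strip())
        ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(ids) != n:
        raise InputError(f"expected {n} rows, found {len(ids)}")
    return tuple(ids), np.array(rows, dtype=float)


def write_outputs(
    out_dir: str | Path,
    grouping: Optional[GroupAssignment] = None,
    sdps=None,
    tree=None,
    dist=None,
) -> dict[str, Path]:
    """Write the standard result files into ``out_dir``.

    Produces ``groups.tsv`` (id -> group), ``sdps.tsv`` (1-based columns
    with Z-scores), ``tree.nwk`` (UPGMA tree with branch lengths) and
    ``distances.phy`` (square PHYLIP matrix), for whichever inputs are
    given.  Returns the mapping of logical name to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if grouping is not None:
        p = out / "groups.tsv"
        write_groups(grouping, p)
        written["groups"] = p
    if sdps is not None:
        p = out / "sdps.tsv"
        write_sdp_list(sdps, p)
        written["sdps"] = p
    if tree is not None:
        p = out / "tree.nwk"
        with open(p, "w") as fh:
            fh.write(tree.to_newick() + "\n")
        written["tree"] = p
    if dist is not None:
        p = out / "distances.phy"
        write_distance_matrix(dist.ids, dist.values, p)
        written["distances"] = p
    return written
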