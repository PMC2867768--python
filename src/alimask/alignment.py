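"""Aligned-FASTA input/output, alignment validation, masks and exclusion reports.

An :class:`Alignment` is an ordered set of equal-length gapped sequences over
either the nucleotide or the amino-acid alphabet.  A :class:`Mask` records,
per column, whether the column is retained by a masking method; applying a
mask yields the sub-alignment of retained columns.

Internally every coordinate is 0-based half-open; all human-readable output
(exclusion ranges, profile tables) is 1-based inclusive, matching the
convention of common alignment-reporting tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._errors import AlignmentShapeError, AlphabetError, InputError

AlphabetKind = Literal["nucleotide", "amino_acid"]

GAP = "-"

#: Canonical residue alphabets (order fixed; used for integer encoding).
NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: IUPAC ambiguity codes.  Ambiguous characters are scored like gaps
#: (see :mod:`alimask.scoring`), for nucleotides and amino acids alike.
NUC_AMBIGUITY = "NRYSWKMBDHV"
AA_AMBIGUITY = "XBZJ"


def residues_for(kind: AlphabetKind) -> str:
    return NUCLEOTIDES if kind == "nucleotide" else AMINO_ACIDS


def ambiguity_for(kind: AlphabetKind) -> str:
    return NUC_AMBIGUITY if kind == "nucleotide" else AA_AMBIGUITY


@dataclass(frozen=True)
class Alignment:
    """A validated multiple sequence alignment.

    Parameters
    ----------
    ids
        Unique, non-empty sequence identifiers, one per row.
    rows
        Equal-length upper-case strings over the declared alphabet, its
        ambiguity codes and ``'-'``.
    alphabet_kind
        ``"nucleotide"`` or ``"amino_acid"``.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    alphabet_kind: AlphabetKind

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise InputError("an alignment needs at least 2 sequences")
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids) or any(not i for i in self.ids):
            raise InputError("sequence ids must be unique and non-empty")
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentShapeError("alignment must have at least one column")
        if any(len(r) != length for r in self.rows):
            raise AlignmentShapeError("alignment rows have unequal lengths")
        legal = set(residues_for(self.alphabet_kind)) | set(
            ambiguity_for(self.alphabet_kind)
        ) | {GAP}
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - legal
            if bad:
                raise AlphabetError(
                    f"sequence {rid!r} contains characters outside the "
                    f"{self.alphabet_kind} alphabet: {sorted(bad)}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        """Number of columns L."""
        return len(self.rows[0])

    def to_indices(self) -> np.ndarray:
        """Encode as an ``(n_rows, L)`` int8 array.

        Residues map to their index in the canonical alphabet; gaps and
        ambiguity codes map to ``len(alphabet)`` (a single "gap-like" code,
        since both are scored identically).
        """
        residues = residues_for(self.alphabet_kind)
        gap_code = len(residues)
        lut = np.full(128, -1, dtype=np.int8)
        for i, ch in enumerate(residues):
            lut[ord(ch)] = i
        for ch in ambiguity_for(self.alphabet_kind) + GAP:
            lut[ord(ch)] = gap_code
        arr = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        return lut[arr].reshape(self.n_rows, self.length)

    def column(self, j: int) -> str:
        """Column *j* (0-based) as a string, one character per row."""
        return "".join(row[j] for row in self.rows)


@dataclass(frozen=True)
class Mask:
    """Per-column retained/excluded flags for an alignment of matching length."""

    retained: tuple[bool, ...]

    @property
    def length(self) -> int:
        return len(self.retained)

    @property
    def n_retained(self) -> int:
        return sum(self.retained)

    @property
    def n_excluded(self) -> int:
        return self.length - self.n_retained

    def excluded_columns(self) -> list[int]:
        """0-based indices of excluded columns, ascending."""
        return [i for i, keep in enumerate(self.retained) if not keep]

    @classmethod
    def from_array(cls, retained: Iterable[bool]) -> "Mask":
        return cls(tuple(bool(x) for x in retained))


def _normalize(seq: str, kind: AlphabetKind) -> str:
    seq = seq.upper().replace(".", GAP)
    if kind == "nucleotide":
        seq = seq.replace("U", "T")
    return seq


def read_fasta(path: str | Path, alphabet_kind: AlphabetKind) -> Alignment:
    """Read an aligned FASTA file into a validated :class:`Alignment`.

    Characters are upper-cased, ``'.'`` is normalized to ``'-'`` and, for
    nucleotide data, ``U`` to ``T``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise InputError(f"{path}: need at least 2 FASTA records, got {len(records)}")
    ids = tuple(r.id for r in records)
    rows = tuple(_normalize(str(r.seq), alphabet_kind) for r in records)
    return Alignment(ids=ids, rows=rows, alphabet_kind=alphabet_kind)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    """Write the alignment as FASTA, 80-column wrapped, order preserved."""
    records = [
        SeqRecord(Seq(row), id=rid, description="") for rid, row in zip(aln.ids, aln.rows)
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=80)
        writer.write_file(records)


class EmptyMaskWarning(UserWarning):
    """Raised (as a warning) when applying a mask retains zero columns."""


def apply_mask(aln: Alignment, mask: Mask) -> Alignment:
    """Return the alignment restricted to the retained columns, order preserved.

    A mask that excludes everything yields a 0-length alignment and emits
    :class:`EmptyMaskWarning`; downstream writers accept it but most
    phylogenetic programs will not.
    """
    if mask.length != aln.length:
        raise AlignmentShapeError(
            f"mask length {mask.length} != alignment length {aln.length}"
        )
    keep = [i for i, flag in enumerate(mask.retained) if flag]
    if not keep:
        warnings.warn(
            "mask excludes every column; result has length 0", EmptyMaskWarning
        )
        empty = object.__new__(Alignment)
        object.__setattr__(empty, "ids", aln.ids)
        object.__setattr__(empty, "rows", tuple("" for _ in aln.rows))
        object.__setattr__(empty, "alphabet_kind", aln.alphabet_kind)
        return empty
    rows = tuple("".join(row[i] for i in keep) for row in aln.rows)
    return Alignment(ids=aln.ids, rows=rows, alphabet_kind=aln.alphabet_kind)


def excluded_ranges(mask: Mask) -> list[tuple[int, int]]:
    """Excluded columns as 1-based inclusive ``(start, end)`` ranges, ascending."""
    ranges: list[tuple[int, int]] = []
    for col in mask.excluded_columns():
        pos = col + 1
        if ranges and ranges[-1][1] == pos - 1:
            ranges[-1] = (ranges[-1][0], pos)
        else:
            ranges.append((pos, pos))
    return ranges


def format_ranges(ranges: Sequence[tuple[int, int]]) -> str:
    return ", ".join(f"{a}-{b}" if a != b else f"{a}" for a, b in ranges)


def write_exclusion_ranges(mask: Mask, path: str | Path) -> None:
    """Write excluded columns as 1-based inclusive ranges (``"4-6, 9"`` style)."""
    with open(path, "w") as fh:
        fh.write(format_ranges(excluded_ranges(mask)) + "\n")


def parse_exclusion_ranges(path: str | Path, length: int) -> Mask:
    """Re-read an exclusion-range file into a :class:`Mask` of the given length."""
    text = Path(path).read_text().strip()
    retained = [True] * length
    if text:
        for token in text.split(","):
            token = token.strip()
            if "-" in token:
                a, b = token.split("-")
                start, end = int(a), int(b)
            else:
                start = end = int(token)
            if not (1 <= start <= end <= length):
                raise InputError(f"range {token!r} outside 1..{length}")
            for pos in range(start, end + 1):
                retained[pos - 1] = False
    return Mask.from_array(retained)


def write_profile_table(
    scores: Sequence[float], mask: Mask, path: str | Path
) -> None:
    """Write a per-position table: 1-based column, consensus score, retained flag."""
    if len(scores) != mask.length:
        raise AlignmentShapeError("profile and mask lengths differ")
    with open(path, "w") as fh:
        fh.write("column\tscore\tretained\n")
        for i, (s, keep) in enumerate(zip(scores, mask.retained), start=1):
            fh.write(f"{i}\t{s:.6f}\t{int(keep)}\n")
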