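"""Substitution matrices and single-site / sliding-window similarity scores.

Pairwise similarity within a window of width ``w`` starting at column ``k``
is the sum of per-site scores,

    S(k) = sum_{l=k}^{k+w-1} q(i_l, j_l),

where ``q`` is a residue-pair score from an empirical substitution matrix
(BLOSUM62 by default for amino acids; PAM250, PAM500 and an identity MATCH
matrix are alternatives).  Three site-level rules extend ``q`` beyond
residue pairs:

* residue vs residue      -> the matrix entry Q_ij;
* gap or ambiguity code vs residue -> the matrix's stop-codon ('*') score
  for that residue (the "indel row");
* gap/ambiguity vs gap/ambiguity   -> ``c / w``, where ``c`` is the cutoff
  of the null distribution, so that a window of matching indels scores
  exactly ``c`` and is never called non-random.

Matrices are read from the NCBI-format tables shipped with ``biotite``;
the MATCH / NUC_MATCH identity matrices (match=1, mismatch=0, indel row 0)
are constructed directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix as _BiotiteMatrix

from ._errors import AlphabetError, ConfigurationError
from .alignment import (
    AMINO_ACIDS,
    GAP,
    NUCLEOTIDES,
    AA_AMBIGUITY,
    NUC_AMBIGUITY,
)

MATRIX_NAMES = ("MATCH", "BLOSUM62", "PAM250", "PAM500", "NUC_MATCH")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue-pair score table with an indel (stop-codon) row.

    ``scores[i, j]`` is the score of residues ``residues[i]`` vs
    ``residues[j]``; ``indel[i]`` the score of a gap (or ambiguity code)
    against ``residues[i]``.
    """

    name: str
    residues: str
    scores: np.ndarray
    indel: np.ndarray

    def __post_init__(self) -> None:
        if not np.array_equal(self.scores, self.scores.T):
            raise ConfigurationError(f"{self.name}: matrix is not symmetric")
        if not (np.isfinite(self.scores).all() and np.isfinite(self.indel).all()):
            raise ConfigurationError(f"{self.name}: non-finite entries")
        if len(self.indel) != len(self.residues):
            raise ConfigurationError(f"{self.name}: incomplete indel row")

    @property
    def is_nucleotide(self) -> bool:
        return self.name == "NUC_MATCH"

    def score(self, a: str, b: str) -> float:
        """Residue-residue entry Q_ab (no gap handling; see :func:`site_score`)."""
        return float(self.scores[self.residues.index(a), self.residues.index(b)])

    def full_table(self, c: float, w: int) -> np.ndarray:
        """``(K+1, K+1)`` table over residue codes plus the gap-like code K.

        Row/column ``K`` carries the indel scores and the ``c/w`` gap-gap
        score; used for vectorized window scoring of encoded alignments.
        """
        k = len(self.residues)
        table = np.empty((k + 1, k + 1), dtype=float)
        table[:k, :k] = self.scores
        table[k, :k] = self.indel
        table[:k, k] = self.indel
        table[k, k] = c / w
        return table


def _from_biotite(name: str) -> SubstitutionMatrix:
    alph = ProteinSequence.alphabet
    m = _BiotiteMatrix(alph, alph, name)
    arr = m.score_matrix().astype(float)
    symbols = list(alph)
    idx = [symbols.index(ch) for ch in AMINO_ACIDS]
    stop = symbols.index("*")
    return SubstitutionMatrix(
        name=name,
        residues=AMINO_ACIDS,
        scores=arr[np.ix_(idx, idx)],
        indel=arr[stop, idx],
    )


def _identity(name: str, residues: str) -> SubstitutionMatrix:
    k = len(residues)
    return SubstitutionMatrix(
        name=name,
        residues=residues,
        scores=np.eye(k, dtype=float),
        indel=np.zeros(k, dtype=float),
    )


def load_matrix(name: str) -> SubstitutionMatrix:
    """Load a supported substitution matrix by name (case-insensitive).

    ``BLOSUM62``, ``PAM250`` and ``PAM500`` are the standard NCBI integer
    log-odds tables, restricted to the 20 amino acids, with the ``'*'``
    row as the indel score.  ``MATCH`` (amino acid) and ``NUC_MATCH``
    (nucleotide) are identity matrices: match=1, mismatch=0, indel row 0.
    """
    key = name.upper()
    if key not in MATRIX_NAMES:
        raise ConfigurationError(
            f"unknown matrix {name!r}; supported: {', '.join(MATRIX_NAMES)}"
        )
    if key == "MATCH":
        return _identity("MATCH", AMINO_ACIDS)
    if key == "NUC_MATCH":
        return _identity("NUC_MATCH", NUCLEOTIDES)
    return _from_biotite(key)


def _gap_like(ch: str, m: SubstitutionMatrix) -> bool:
    ambiguity = NUC_AMBIGUITY if m.is_nucleotide else AA_AMBIGUITY
    return ch == GAP or ch in ambiguity


def site_score(
    m: SubstitutionMatrix,
    a: str,
    b: str,
    c: float | None = None,
    w: int | None = None,
) -> float:
    """Score one aligned site under the matrix plus the gap/indel rules.

    ``c`` and ``w`` are required only when both characters are gap-like
    (gap or ambiguity code), in which case the site scores ``c/w``.
    """
    a_gap, b_gap = _gap_like(a, m), _gap_like(b, m)
    if a_gap and b_gap:
        if c is None or w is None:
            raise ConfigurationError("gap-gap site needs the cutoff c and width w")
        return c / w
    if a_gap or b_gap:
        residue = b if a_gap else a
        if residue not in m.residues:
            raise AlphabetError(f"character {residue!r} not in {m.name} alphabet")
        return float(m.indel[m.residues.index(residue)])
    for ch in (a, b):
        if ch not in m.residues:
            raise AlphabetError(f"character {ch!r} not in {m.name} alphabet")
    return m.score(a, b)


@dataclass(frozen=True)
class WindowScore:
    """Similarity score S(k) of one window placement (1-based start k)."""

    k: int
    w: int
    value: float


def window_score(
    m: SubstitutionMatrix,
    row_i: str,
    row_j: str,
    k: int = 1,
    w: int = 6,
    c: float = 0.0,
) -> WindowScore:
    """S(k): sum of site scores over the ``w`` columns starting at 1-based ``k``."""
    if k < 1 or k + w - 1 > min(len(row_i), len(row_j)):
        raise ConfigurationError(
            f"window [{k}, {k + w - 1}] exceeds row length "
            f"{min(len(row_i), len(row_j))}"
        )
    total = 0.0
    for a, b in zip(row_i[k - 1 : k - 1 + w], row_j[k - 1 : k - 1 + w]):
        total += site_score(m, a, b, c=c, w=w)
    return WindowScore(k=k, w=w, value=total)


def pair_site_scores(
    m: SubstitutionMatrix,
    codes_i: np.ndarray,
    codes_j: np.ndarray,
    c: float,
    w: int,
) -> np.ndarray:
    """Vectorized per-column site scores for two encoded rows."""
    return m.full_table(c, w)[codes_i, codes_j]


def sliding_window_scores(site_scores: np.ndarray, w: int) -> np.ndarray:
    """All window sums S(k), k = 1..L-w+1, from per-site scores (step 1)."""
    length = len(site_scores)
    if w > length:
        raise ConfigurationError(f"window width {w} exceeds length {length}")
    cs = np.concatenate(([0.0], np.cumsum(site_scores)))
    return cs[w:] - cs[:-w]
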