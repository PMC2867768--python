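"""Rule-based conserved-block masking (GBLOCKS-style comparator).

A deliberately simple, fully configurable reimplementation of the classic
rule set: per-column conservation classes from the modal residue fraction,
a gap rule with three modes, rejection of long non-conserved stretches,
trimming of candidate blocks to highly conserved flanks, and a minimum
block length.  It serves as the non-parametric comparator to the
sliding-window profiler; bit-compatibility with the original GBLOCKS
program is not a goal.

Gap modes (fraction of rows holding a gap in the column):
  * ``none`` — no gaps tolerated;
  * ``half`` — fewer than 50% of the rows may hold a gap;
  * ``all``  — gaps never disqualify a column.
Relaxing the mode (none -> half -> all) can only grow the retained set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from ._errors import ConfigurationError
from .alignment import GAP, Alignment, Mask, ambiguity_for

GapMode = Literal["none", "half", "all"]

NONCONSERVED, CONSERVED, HIGHLY_CONSERVED = 0, 1, 2


@dataclass(frozen=True)
class BlockFilterConfig:
    """Thresholds of the rule-based filter.

    A column is *conserved* when strictly more than ``conserved_threshold``
    of the rows carry the modal non-gap residue ("half the rows plus one"
    at the 0.5 default), and *highly conserved* at
    ``highly_conserved_threshold`` or above.  Runs of more than
    ``max_nonconserved_run`` contiguous non-conserved columns break blocks;
    surviving blocks are trimmed inward to highly conserved flanks and must
    reach ``min_block_length``.
    """

    conserved_threshold: float = 0.5
    highly_conserved_threshold: float = 0.85
    max_nonconserved_run: int = 8
    min_block_length: int = 10
    gap_mode: GapMode = "half"

    def __post_init__(self) -> None:
        if not (0 < self.conserved_threshold <= self.highly_conserved_threshold <= 1):
            raise ConfigurationError(
                "need 0 < conserved_threshold <= highly_conserved_threshold <= 1"
            )
        if self.min_block_length < 1 or self.max_nonconserved_run < 0:
            raise ConfigurationError("invalid block-length/run settings")
        if self.gap_mode not in ("none", "half", "all"):
            raise ConfigurationError(f"unknown gap mode {self.gap_mode!r}")


def gap_allowed(column: Sequence[str], n_rows: int, gap_mode: GapMode) -> bool:
    """Whether the column's gap content is tolerated under the given mode."""
    n_gaps = sum(1 for ch in column if ch == GAP)
    if gap_mode == "none":
        return n_gaps == 0
    if gap_mode == "half":
        return n_gaps < n_rows / 2
    if gap_mode == "all":
        return True
    raise ConfigurationError(f"unknown gap mode {gap_mode!r}")


def classify_conservation(
    aln: Alignment, cfg: BlockFilterConfig
) -> np.ndarray:
    """Per-column labels 0/1/2 (non/conserved/highly) from the modal residue.

    Gaps and ambiguity codes never count toward the modal residue; a column
    with no countable residue is non-conserved.  The gap rule is applied
    separately in :func:`run_block_filter`.
    """
    skip = set(ambiguity_for(aln.alphabet_kind)) | {GAP}
    n = aln.n_rows
    labels = np.zeros(aln.length, dtype=np.int8)
    for j in range(aln.length):
        counts = Counter(ch for ch in aln.column(j) if ch not in skip)
        if not counts:
            continue
        frac = counts.most_common(1)[0][1] / n
        if frac >= cfg.highly_conserved_threshold:
            labels[j] = HIGHLY_CONSERVED
        elif frac > cfg.conserved_threshold:
            labels[j] = CONSERVED
    return labels


def run_block_filter(aln: Alignment, cfg: BlockFilterConfig | None = None) -> Mask:
    """Apply the full rule set and return the retained-column mask.

    Steps: (1) columns failing the gap rule are demoted to non-conserved;
    (2) runs of more than ``max_nonconserved_run`` contiguous non-conserved
    columns are rejected outright; (3) each remaining candidate segment is
    trimmed inward until it starts and ends on a highly conserved column;
    (4) segments shorter than ``min_block_length`` are rejected.
    """
    cfg = cfg or BlockFilterConfig()
    labels = classify_conservation(aln, cfg)
    for j in range(aln.length):
        if labels[j] != NONCONSERVED and not gap_allowed(
            aln.column(j), aln.n_rows, cfg.gap_mode
        ):
            labels[j] = NONCONSERVED

    length = aln.length
    rejected = np.zeros(length, dtype=bool)
    j = 0
    while j < length:
        if labels[j] == NONCONSERVED:
            k = j
            while k < length and labels[k] == NONCONSERVED:
                k += 1
            if k - j > cfg.max_nonconserved_run:
                rejected[j:k] = True
            j = k
        else:
            j += 1

    retained = np.zeros(length, dtype=bool)
    j = 0
    while j < length:
        if rejected[j]:
            j += 1
            continue
        k = j
        while k < length and not rejected[k]:
            k += 1
        # candidate segment [j, k); trim to highly conserved flanks
        a, b = j, k - 1
        while a <= b and labels[a] != HIGHLY_CONSERVED:
            a += 1
        while b >= a and labels[b] != HIGHLY_CONSERVED:
            b -= 1
        if a <= b and b - a + 1 >= cfg.min_block_length:
            retained[a : b + 1] = True
        j = k
    return Mask.from_array(retained)
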