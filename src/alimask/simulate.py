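"""Synthetic alignments with known conserved and randomized sections.

The simulator is the validation surface of the package: it builds
alignments whose columns carry a ground-truth label, so that a mask can be
scored by how many truly randomized columns it excludes (sensitivity) and
how many truly conserved columns it keeps (specificity).

Conserved blocks evolve on a star tree: one ancestral sequence is drawn
from the residue frequencies pi and every row evolves independently per
site under the Proportional model at ``divergence_mu_t``.  Randomized
blocks have every cell i.i.d. from pi — by construction they hold nothing
but compositional similarity, the situation the profiler's null models.
Gaps are injected uniformly at rate ``gap_fraction``, by default only into
randomized blocks so the ground truth stays binary (indel-riddled random
stretches are where real alignments go wrong); ``gaps_in_conserved=True``
allows them everywhere for stress tests.

Defaults emulate a short single-gene alignment: 10 sequences, a 40-column
conserved core at moderate divergence (mu*t = 0.3, about 75% expected
pairwise identity under the Proportional model) flanked by a 20-column
randomized stretch with 10% gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._errors import ConfigurationError, InputError
from .alignment import Alignment, AlphabetKind, Mask, residues_for
from .null_model import FrequencyVector, ProportionalModelConfig, uniform_frequencies

CONSERVED, RANDOMIZED = "conserved", "randomized"

DEFAULT_BLOCKS: tuple[tuple[str, int], ...] = ((CONSERVED, 40), (RANDOMIZED, 20))
DEFAULT_DIVERGENCE_MU_T = 0.3
DEFAULT_GAP_FRACTION = 0.1


@dataclass(frozen=True)
class SimulatedAlignment:
    """Alignment plus per-column ground truth and the generating parameters."""

    alignment: Alignment
    truth: tuple[str, ...]
    params: dict

    def __post_init__(self) -> None:
        if len(self.truth) != self.alignment.length:
            raise InputError("truth length != alignment length")

    def truth_mask(self) -> Mask:
        """The ideal mask: retain conserved columns, exclude randomized ones."""
        return Mask.from_array(label == CONSERVED for label in self.truth)


def simulate_alignment(
    n_rows: int = 10,
    blocks: Sequence[tuple[str, int]] = DEFAULT_BLOCKS,
    pi: FrequencyVector | None = None,
    divergence_mu_t: float = DEFAULT_DIVERGENCE_MU_T,
    gap_fraction: float = DEFAULT_GAP_FRACTION,
    seed: int = 0,
    alphabet_kind: AlphabetKind = "amino_acid",
    gaps_in_conserved: bool = False,
) -> SimulatedAlignment:
    """Build an alignment of labelled conserved / randomized blocks.

    Deterministic given ``seed``.  ``pi`` defaults to the uniform
    distribution over the residue alphabet of ``alphabet_kind``.
    """
    if n_rows < 2:
        raise InputError("need at least 2 rows")
    if not blocks or any(length < 1 for _, length in blocks):
        raise ConfigurationError("blocks need positive lengths")
    if not 0.0 <= gap_fraction < 1.0:
        raise ConfigurationError("gap_fraction must be in [0, 1)")
    if divergence_mu_t < 0:
        raise ConfigurationError("divergence_mu_t must be nonnegative")
    labels = [label for label, _ in blocks]
    if any(label not in (CONSERVED, RANDOMIZED) for label in labels):
        raise ConfigurationError(f"block labels must be {CONSERVED!r}/{RANDOMIZED!r}")

    residues = residues_for(alphabet_kind)
    if pi is None:
        pi = uniform_frequencies(residues)
    if pi.residues != residues:
        raise ConfigurationError("pi alphabet does not match alphabet_kind")
    probs = pi.probabilities
    rng = np.random.default_rng(seed)
    p_same = ProportionalModelConfig(mu_t=divergence_mu_t).identity_probability

    columns: list[np.ndarray] = []  # (n_rows,) residue codes, -1 = gap
    truth: list[str] = []
    for label, length in blocks:
        if label == CONSERVED:
            ancestor = rng.choice(len(probs), size=length, p=probs)
            block = np.tile(ancestor, (n_rows, 1))
            changed = rng.random((n_rows, length)) >= p_same
            fresh = rng.choice(len(probs), size=(n_rows, length), p=probs)
            block = np.where(changed, fresh, block)
        else:
            block = rng.choice(len(probs), size=(n_rows, length), p=probs)
        if gap_fraction > 0 and (label == RANDOMIZED or gaps_in_conserved):
            gaps = rng.random((n_rows, length)) < gap_fraction
            block = np.where(gaps, -1, block)
        columns.append(block)
        truth.extend([label] * length)

    full = np.concatenate(columns, axis=1)
    lookup = np.array(list(residues + "-"))
    rows = tuple("".join(lookup[row]) for row in full)  # -1 indexes the gap
    aln = Alignment(
        ids=tuple(f"seq{i + 1}" for i in range(n_rows)),
        rows=rows,
        alphabet_kind=alphabet_kind,
    )
    params = {
        "n_rows": n_rows,
        "blocks": tuple(blocks),
        "pi": tuple(np.round(probs, 12)),
        "divergence_mu_t": divergence_mu_t,
        "gap_fraction": gap_fraction,
        "seed": seed,
        "alphabet_kind": alphabet_kind,
        "gaps_in_conserved": gaps_in_conserved,
    }
    return SimulatedAlignment(alignment=aln, truth=tuple(truth), params=params)


def confusion_vs_truth(
    mask: Mask, truth: Sequence[str]
) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) of a mask against column labels.

    Sensitivity: fraction of randomized columns excluded.  Specificity:
    fraction of conserved columns retained.  ``None`` when the class is
    absent (undefined rather than 0/0).
    """
    if mask.length != len(truth):
        raise InputError("mask and truth lengths differ")
    randomized = [i for i, t in enumerate(truth) if t == RANDOMIZED]
    conserved = [i for i, t in enumerate(truth) if t == CONSERVED]
    sens = (
        sum(1 for i in randomized if not mask.retained[i]) / len(randomized)
        if randomized
        else None
    )
    spec = (
        sum(1 for i in conserved if mask.retained[i]) / len(conserved)
        if conserved
        else None
    )
    return sens, spec


def write_truth(sim: SimulatedAlignment, path: str | Path) -> None:
    """Sidecar tab-separated truth file: 1-based column, label."""
    with open(path, "w") as fh:
        fh.write("column\tlabel\n")
        for i, label in enumerate(sim.truth, start=1):
            fh.write(f"{i}\t{label}\n")


def read_truth(path: str | Path) -> tuple[str, ...]:
    labels: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                labels.append(line.rstrip("\n").split("\t")[1])
    return tuple(labels)
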