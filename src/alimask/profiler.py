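"""Sliding-window randomness profiling of alignment sequence pairs.

For every sampled sequence pair a window of width ``w`` slides over the
alignment in steps of one column; each placement's similarity score S(k)
is compared with the cutoff c of the null distribution of randomly similar
sequences.  A window call is +1 if S(k) > c (similarity exceeds chance)
and -1 otherwise; the per-column score of the pair is the mean call over
the windows covering that column, and the consensus profile is the mean of
the pair scores over all sampled pairs.  A column is retained iff its
consensus score is positive — ties look random and are excluded.

Amino-acid mode computes a single global null from the residue composition
of the whole alignment (the complex bootstrap is expensive, and amino-acid
composition is comparatively homogeneous).  Nucleotide mode adapts to the
heterogeneous base composition among sequences by building one null per
pair from the pooled base frequencies of the two sequences compared,
with a lighter bootstrap (the per-pair nulls multiply the work by the
number of pairs).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._errors import ConfigurationError, InputError
from .alignment import Alignment, Mask
from .null_model import (
    Cutoff,
    ProportionalModelConfig,
    collect_frequencies,
    compute_cutoff,
    pooled_frequencies,
    resample_frequency_vectors,
    sample_null_scores,
)
from .scoring import (
    SubstitutionMatrix,
    load_matrix,
    pair_site_scores,
    sliding_window_scores,
)

DEFAULT_WINDOW = 6
DEFAULT_ALPHA = 0.95
DEFAULT_MAX_PAIRS = 2000

#: Per-pair (nucleotide) nulls use a lighter bootstrap than the single
#: global amino-acid null: 10 x 10 x 100 = 10,000 scores per pair.
NUC_N_BOOT = 10
NUC_N_DELETE_HALF = 10


@dataclass(frozen=True)
class PairProfile:
    """Window calls and per-column scores for one sequence pair."""

    pair: tuple[int, int]
    window_calls: np.ndarray  # +1 / -1 per window start, length L - w + 1
    position_scores: np.ndarray  # mean call over covering windows, length L


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-column mean of pair position scores; retained iff mean > 0."""

    scores: np.ndarray
    mask: Mask


@dataclass(frozen=True)
class ProfileResult:
    """End-to-end profiling output: consensus, mask and null metadata."""

    consensus: ConsensusProfile
    mask: Mask
    cutoff: Cutoff | None
    null_meta: dict

    def __iter__(self):
        return iter((self.consensus, self.mask, self.null_meta))


def select_pairs(
    n_rows: int, max_pairs: int = DEFAULT_MAX_PAIRS, seed: int = 0
) -> list[tuple[int, int]]:
    """All row pairs, or a uniform sample of ``max_pairs`` distinct ones.

    Deterministic given ``seed``; pairs are (i, j) with i < j, 0-based.
    """
    if n_rows < 2:
        raise InputError("need at least 2 rows to form pairs")
    all_pairs = [(i, j) for i in range(n_rows) for j in range(i + 1, n_rows)]
    if len(all_pairs) <= max_pairs:
        return all_pairs
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(all_pairs), size=max_pairs, replace=False)
    return [all_pairs[i] for i in sorted(chosen)]


def _coverage(length: int, w: int) -> np.ndarray:
    """Number of windows covering each column (1 at the ends, up to w inside)."""
    return np.convolve(np.ones(length - w + 1), np.ones(w))


def profile_pair(
    aln: Alignment,
    pair: tuple[int, int],
    m: SubstitutionMatrix,
    c: Cutoff,
    w: int = DEFAULT_WINDOW,
    _codes: np.ndarray | None = None,
) -> PairProfile:
    """Profile one pair: slide the window, call windows against the cutoff,
    average the +/-1 calls per column over its covering windows."""
    if w > aln.length:
        raise ConfigurationError(f"window {w} wider than alignment ({aln.length})")
    codes = aln.to_indices() if _codes is None else _codes
    i, j = pair
    site = pair_site_scores(m, codes[i], codes[j], c.c, w)
    s_k = sliding_window_scores(site, w)
    calls = np.where(s_k > c.c, 1.0, -1.0)
    position = np.convolve(calls, np.ones(w)) / _coverage(aln.length, w)
    return PairProfile(pair=pair, window_calls=calls, position_scores=position)


def aggregate_profiles(
    profiles: Sequence[PairProfile], length: int
) -> ConsensusProfile:
    """Mean of per-column scores across pairs; retained iff strictly positive."""
    if len(profiles) == 0:
        raise InputError("no pair profiles to aggregate")
    stack = np.stack([p.position_scores for p in profiles])
    if stack.shape[1] != length:
        raise InputError("profile length mismatch")
    mean = stack.mean(axis=0)
    return ConsensusProfile(scores=mean, mask=Mask.from_array(mean > 0))


def _resolve_matrix(matrix_name: str, aln: Alignment) -> SubstitutionMatrix:
    name = matrix_name.upper()
    if aln.alphabet_kind == "nucleotide" and name == "MATCH":
        name = "NUC_MATCH"
    m = load_matrix(name)
    if aln.alphabet_kind == "nucleotide" and not m.is_nucleotide:
        raise ConfigurationError(
            f"matrix {matrix_name!r} is an amino-acid matrix; nucleotide "
            "alignments use MATCH scoring"
        )
    return m


def profile_alignment(
    aln: Alignment,
    matrix_name: str = "BLOSUM62",
    w: int = DEFAULT_WINDOW,
    alpha: float = DEFAULT_ALPHA,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
    mu_t: float = math.inf,
    n_boot: int | None = None,
    n_delete_half: int | None = None,
    scores_per_resample: int = 100,
) -> ProfileResult:
    """Run the full profiler and return consensus profile, mask and metadata.

    Amino acid: one global null (complex bootstrap of the alignment-wide
    residue frequencies) -> cutoff -> profile all sampled pairs.
    Nucleotide: a per-pair null from the pooled base composition of the two
    sequences, then identical profiling.  All randomness derives from
    ``seed``.
    """
    if w > aln.length:
        raise ConfigurationError(f"window {w} wider than alignment ({aln.length})")
    m = _resolve_matrix(matrix_name, aln)
    cfg = ProportionalModelConfig(mu_t=mu_t)
    nucleotide = aln.alphabet_kind == "nucleotide"
    if n_boot is None:
        n_boot = NUC_N_BOOT if nucleotide else 100
    if n_delete_half is None:
        n_delete_half = NUC_N_DELETE_HALF if nucleotide else 100

    ss = np.random.SeedSequence(seed)
    seed_pairs, seed_boot, seed_null = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    pairs = select_pairs(aln.n_rows, max_pairs=max_pairs, seed=seed_pairs)
    codes = aln.to_indices()

    meta: dict = {
        "matrix": m.name,
        "w": w,
        "alpha": alpha,
        "mu_t": mu_t,
        "n_pairs": len(pairs),
        "n_boot": n_boot,
        "n_delete_half": n_delete_half,
        "scores_per_resample": scores_per_resample,
        "seed": seed,
    }

    profiles: list[PairProfile] = []
    if nucleotide:
        # per-pair null adapted to the base composition of the two sequences
        cutoffs = []
        for idx, pair in enumerate(pairs):
            pi = pooled_frequencies(aln, pair)
            vectors = resample_frequency_vectors(
                pi, n_boot=n_boot, n_delete_half=n_delete_half,
                seed=(seed_boot + idx) % (2**31),
            )
            nd = sample_null_scores(
                vectors, m, w=w, cfg=cfg,
                scores_per_resample=scores_per_resample,
                seed=(seed_null + idx) % (2**31),
            )
            cut = compute_cutoff(nd, alpha)
            cutoffs.append(cut.c)
            profiles.append(profile_pair(aln, pair, m, cut, w=w, _codes=codes))
        # the reported cutoff is the median over per-pair cutoffs
        cutoff = Cutoff(alpha=alpha, c=float(np.median(cutoffs)))
        meta["n_null_scores_per_pair"] = n_boot * n_delete_half * scores_per_resample
        meta["cutoff"] = cutoff.c
    else:
        pi = collect_frequencies(aln)
        vectors = resample_frequency_vectors(
            pi, n_boot=n_boot, n_delete_half=n_delete_half, seed=seed_boot
        )
        nd = sample_null_scores(
            vectors, m, w=w, cfg=cfg,
            scores_per_resample=scores_per_resample, seed=seed_null,
        )
        nd = dataclasses.replace(
            nd, n_boot=n_boot, n_delete_half=n_delete_half
        )
        cutoff = compute_cutoff(nd, alpha)
        meta["n_null_scores"] = nd.n_scores
        meta["cutoff"] = cutoff.c
        for pair in pairs:
            profiles.append(profile_pair(aln, pair, m, cutoff, w=w, _codes=codes))

    consensus = aggregate_profiles(profiles, aln.length)
    return ProfileResult(
        consensus=consensus, mask=consensus.mask, cutoff=cutoff, null_meta=meta
    )
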