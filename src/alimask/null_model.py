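"""Null distribution of window scores of randomly similar sequences.

The profiler needs to know how large a window score can get by chance
between sequences that share residue composition but no homology.  That
null is built in three steps:

1. residue frequencies pi are collected from the complete observed
   alignment (gaps and ambiguity codes excluded);
2. a complex bootstrap spreads the null over compositional uncertainty:
   ``n_boot`` multinomial redraws of the original residue sample, each
   followed by ``n_delete_half`` half-sized subsamples drawn without
   replacement (10,000 frequency vectors at the defaults 100 x 100);
3. from each frequency vector, pairs of window-length sequences are
   generated under the Proportional model and scored, yielding
   ``n_vectors x scores_per_resample`` null scores (1,000,000 at the
   default 100 scores per resample).

The Proportional model is the amino-acid analogue of a Poisson/F81-type
process: the probability of ending in residue j after rate-time mu*t is

    P_ij(t) = exp(-mu t) * delta_ij + pi_j * (1 - exp(-mu t)),

so ``mu_t = 0`` copies the first sequence and ``mu_t = inf`` (the default
for null generation) draws both sequences independently from pi — randomly
similar sequences carry no phylogenetic signal.

The cutoff c(alpha) is the smallest null score whose empirical cumulative
frequency reaches alpha; an observed window must *exceed* c to be called
non-random (ties count toward the null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._errors import InputError
from .alignment import Alignment, residues_for
from .scoring import SubstitutionMatrix

DEFAULT_N_BOOT = 100
DEFAULT_N_DELETE_HALF = 100
DEFAULT_SCORES_PER_RESAMPLE = 100


@dataclass(frozen=True)
class FrequencyVector:
    """Residue probabilities pi over a fixed residue alphabet.

    ``total_count`` is the number of residues the frequencies were estimated
    from (needed by the bootstrap); it is ``None`` for derived vectors.
    """

    probabilities: np.ndarray
    residues: str
    total_count: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if len(p) != len(self.residues):
            raise InputError("frequency vector length != alphabet size")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise InputError("probabilities must be >= 0 and sum to 1")
        object.__setattr__(self, "probabilities", p)


def uniform_frequencies(residues: str) -> FrequencyVector:
    k = len(residues)
    return FrequencyVector(np.full(k, 1.0 / k), residues)


def collect_frequencies(aln: Alignment) -> FrequencyVector:
    """Residue frequencies of the complete alignment.

    Gaps and ambiguity codes do not count; the returned vector carries the
    total residue count for later resampling.
    """
    residues = residues_for(aln.alphabet_kind)
    codes = aln.to_indices().ravel()
    counts = np.bincount(codes[codes < len(residues)], minlength=len(residues))
    total = int(counts.sum())
    if total == 0:
        raise InputError("alignment contains no unambiguous residues")
    return FrequencyVector(counts / total, residues, total_count=total)


def pooled_frequencies(aln: Alignment, rows: Sequence[int]) -> FrequencyVector:
    """Frequencies pooled over a subset of rows (used for per-pair nucleotide nulls)."""
    residues = residues_for(aln.alphabet_kind)
    codes = aln.to_indices()[list(rows)].ravel()
    counts = np.bincount(codes[codes < len(residues)], minlength=len(residues))
    total = int(counts.sum())
    if total == 0:
        raise InputError("selected rows contain no unambiguous residues")
    return FrequencyVector(counts / total, residues, total_count=total)


def resample_frequency_vectors(
    pi: FrequencyVector,
    total_count: int | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    n_delete_half: int = DEFAULT_N_DELETE_HALF,
    seed: int = 0,
) -> list[FrequencyVector]:
    """Complex (delete-half) bootstrap of a residue-frequency sample.

    Each of ``n_boot`` multinomial redraws of the ``total_count`` observed
    residues is subsampled ``n_delete_half`` times to half size without
    replacement (multivariate hypergeometric); the normalized counts of the
    ``n_boot * n_delete_half`` subsamples are returned.  Deterministic given
    ``seed``.
    """
    if total_count is None:
        total_count = pi.total_count
    if total_count is None or total_count < 2:
        raise InputError("total_count must be >= 2")
    rng = np.random.default_rng(seed)
    half = total_count // 2
    out: list[FrequencyVector] = []
    for _ in range(n_boot):
        boot_counts = rng.multinomial(total_count, pi.probabilities)
        for _ in range(n_delete_half):
            sub = rng.multivariate_hypergeometric(boot_counts, half)
            out.append(FrequencyVector(sub / half, pi.residues))
    return out


@dataclass(frozen=True)
class ProportionalModelConfig:
    """Rate-time product mu*t of the Proportional model; ``inf`` = stationarity."""

    mu_t: float = math.inf

    def __post_init__(self) -> None:
        if self.mu_t < 0:
            raise InputError("mu_t must be nonnegative")

    @property
    def identity_probability(self) -> float:
        """exp(-mu t): the chance a site has not changed at all."""
        return 0.0 if math.isinf(self.mu_t) else math.exp(-self.mu_t)


def _draw_categorical(cum: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Row-wise inverse-CDF draw: cum is (..., K) cumulative probs, u uniforms."""
    idx = (u[..., None] > cum[..., None, :]).sum(axis=-1)
    return np.minimum(idx, cum.shape[-1] - 1)


def sample_proportional_pair(
    pi: FrequencyVector,
    cfg: ProportionalModelConfig,
    length: int,
    seed: int = 0,
) -> tuple[str, str]:
    """One pair of randomly similar residue strings of the given length.

    The first string is i.i.d. from pi; per site, the second copies the
    first with probability exp(-mu t) and is otherwise redrawn from pi.
    """
    rng = np.random.default_rng(seed)
    first, second = _sample_pair_codes(pi.probabilities, cfg, length, 1, rng)
    residues = np.frombuffer(pi.residues.encode(), dtype=np.uint8)
    return (
        residues[first[0]].tobytes().decode(),
        residues[second[0]].tobytes().decode(),
    )


def _sample_pair_codes(
    probs: np.ndarray,
    cfg: ProportionalModelConfig,
    length: int,
    n_pairs: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_pairs, length) residue-code arrays for both members of each pair."""
    cum = np.cumsum(probs)
    first = _draw_categorical(cum, rng.random((n_pairs, length)))
    fresh = _draw_categorical(cum, rng.random((n_pairs, length)))
    p_same = cfg.identity_probability
    if p_same > 0.0:
        copy = rng.random((n_pairs, length)) < p_same
        second = np.where(copy, first, fresh)
    else:
        second = fresh
    return first, second


@dataclass(frozen=True)
class NullDistribution:
    """Sorted empirical distribution of window scores of randomly similar pairs."""

    matrix_name: str
    w: int
    scores: np.ndarray
    n_boot: int | None = None
    n_delete_half: int | None = None
    scores_per_resample: int | None = None
    seed: int | None = None
    mu_t: float = math.inf

    def __post_init__(self) -> None:
        s = np.sort(np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "scores", s)

    @property
    def n_scores(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class Cutoff:
    """c(alpha): smallest null score with empirical CDF >= alpha."""

    alpha: float
    c: float


def sample_null_scores(
    freq_vectors: Sequence[FrequencyVector],
    m: SubstitutionMatrix,
    w: int = 6,
    cfg: ProportionalModelConfig = ProportionalModelConfig(),
    scores_per_resample: int = DEFAULT_SCORES_PER_RESAMPLE,
    seed: int = 0,
    _chunk: int = 1000,
) -> NullDistribution:
    """Score ``scores_per_resample`` random pairs of length ``w`` per frequency vector.

    Null sequences contain no gaps, so only the residue block of the matrix
    is used.  Sampling is vectorized over frequency vectors in chunks;
    deterministic given ``seed``.
    """
    if w < 1:
        raise InputError("window width must be >= 1")
    if len(freq_vectors) == 0:
        raise InputError("need at least one frequency vector")
    rng = np.random.default_rng(seed)
    probs = np.stack([fv.probabilities for fv in freq_vectors])
    n_vec, k = probs.shape
    q = m.scores
    p_same = cfg.identity_probability
    chunks: list[np.ndarray] = []
    for start in range(0, n_vec, _chunk):
        block = probs[start : start + _chunk]
        nb = block.shape[0]
        cum = np.cumsum(block, axis=1)  # (nb, K)
        shape = (nb, scores_per_resample * w)
        first = _draw_categorical(cum, rng.random(shape))
        fresh = _draw_categorical(cum, rng.random(shape))
        if p_same > 0.0:
            copy = rng.random(shape) < p_same
            second = np.where(copy, first, fresh)
        else:
            second = fresh
        site = q[first, second].reshape(nb, scores_per_resample, w)
        chunks.append(site.sum(axis=2).ravel())
    return NullDistribution(
        matrix_name=m.name,
        w=w,
        scores=np.concatenate(chunks),
        scores_per_resample=scores_per_resample,
        seed=seed,
        mu_t=cfg.mu_t,
    )


def compute_cutoff(nd: NullDistribution, alpha: float = 0.95) -> Cutoff:
    """Empirical alpha-quantile: the ceil(alpha * n)-th smallest null score."""
    if not 0.0 < alpha < 1.0:
        raise InputError("alpha must be in (0, 1)")
    n = nd.n_scores
    if n == 0:
        raise InputError("empty null distribution")
    rank = math.ceil(alpha * n)  # 1-based
    return Cutoff(alpha=alpha, c=float(nd.scores[rank - 1]))


def save_null_distribution(nd: NullDistribution, path: str | Path) -> None:
    """Persist scores plus metadata as a tab-separated file for reuse."""
    with open(path, "w") as fh:
        fh.write(f"#matrix={nd.matrix_name}\n#w={nd.w}\n#mu_t={nd.mu_t}\n")
        fh.write(f"#seed={nd.seed}\n#scores_per_resample={nd.scores_per_resample}\n")
        fh.write("score\n")
        for s in nd.scores:
            fh.write(f"{float(s)!r}\n")


def load_null_distribution(path: str | Path) -> NullDistribution:
    meta: dict[str, str] = {}
    scores: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
            elif line and line != "score":
                scores.append(float(line))
    def _opt_int(key: str) -> int | None:
        val = meta.get(key, "None")
        return None if val == "None" else int(val)
    return NullDistribution(
        matrix_name=meta.get("matrix", "?"),
        w=int(meta.get("w", "6")),
        scores=np.array(scores),
        scores_per_resample=_opt_int("scores_per_resample"),
        seed=_opt_int("seed"),
        mu_t=float(meta.get("mu_t", "inf")),
    )
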