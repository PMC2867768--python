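"""Null-score generation: frequencies, complex bootstrap, Proportional model, cutoff."""

import math

import numpy as np
import pytest
from scipy import stats

from alimask import (
    Alignment,
    FrequencyVector,
    InputError,
    NullDistribution,
    ProportionalModelConfig,
    collect_frequencies,
    compute_cutoff,
    load_matrix,
    load_null_distribution,
    resample_frequency_vectors,
    sample_null_scores,
    sample_proportional_pair,
    save_null_distribution,
    uniform_frequencies,
)


class TestCollectFrequencies:
    def test_direct_count(self):
        aln = Alignment(ids=("a", "b"), rows=("AA", "AR"),
                        alphabet_kind="amino_acid")
        fv = collect_frequencies(aln)
        assert fv.probabilities[fv.residues.index("A")] == 0.75
        assert fv.probabilities[fv.residues.index("R")] == 0.25
        assert fv.total_count == 4

    def test_gaps_and_ambiguity_excluded(self):
        aln = Alignment(ids=("a", "b"), rows=("A-X", "-AX"),
                        alphabet_kind="amino_acid")
        fv = collect_frequencies(aln)
        assert fv.probabilities[fv.residues.index("A")] == 1.0
        assert fv.total_count == 2

    def test_no_residues_rejected(self):
        aln = Alignment(ids=("a", "b"), rows=("--", "--"),
                        alphabet_kind="amino_acid")
        with pytest.raises(InputError):
            collect_frequencies(aln)


class TestResampleFrequencyVectors:
    def test_default_yields_10000_vectors(self):
        pi = FrequencyVector(np.full(4, 0.25), "ACGT", total_count=400)
        vectors = resample_frequency_vectors(pi, seed=1)
        assert len(vectors) == 10_000

    def test_small_counts(self):
        pi = FrequencyVector(np.full(4, 0.25), "ACGT", total_count=100)
        vectors = resample_frequency_vectors(pi, n_boot=3, n_delete_half=5, seed=1)
        assert len(vectors) == 15
        for v in vectors:
            assert v.probabilities.sum() == pytest.approx(1.0)
            assert (v.probabilities >= 0).all()

    def test_single_resample_valid(self):
        pi = FrequencyVector(np.array([0.5, 0.5]), "AC", total_count=10)
        (v,) = resample_frequency_vectors(pi, n_boot=1, n_delete_half=1, seed=0)
        assert isinstance(v, FrequencyVector)

    def test_determinism(self):
        pi = FrequencyVector(np.full(4, 0.25), "ACGT", total_count=200)
        a = resample_frequency_vectors(pi, n_boot=4, n_delete_half=4, seed=9)
        b = resample_frequency_vectors(pi, n_boot=4, n_delete_half=4, seed=9)
        assert all(np.array_equal(x.probabilities, y.probabilities)
                   for x, y in zip(a, b))

    def test_total_count_too_small(self):
        pi = FrequencyVector(np.array([1.0]), "A")
        with pytest.raises(InputError):
            resample_frequency_vectors(pi, total_count=1, seed=0)


class TestProportionalModel:
    def test_mu_t_zero_copies_first(self):
        pi = uniform_frequencies("ACGT")
        a, b = sample_proportional_pair(pi, ProportionalModelConfig(0.0), 200, seed=3)
        assert a == b

    def test_transition_matrix_row_stochastic(self):
        pi = uniform_frequencies("ARND")
        for mu_t in (0.0, 0.5, 2.0):
            e = math.exp(-mu_t)
            p = e * np.eye(4) + (1 - e) * np.tile(pi.probabilities, (4, 1))
            assert np.allclose(p.sum(axis=1), 1.0)

    def test_stationary_frequencies_recovered(self):
        """mu_t = inf: second-string frequencies match pi within 3 SE."""
        n = 100_000
        pi = FrequencyVector(np.array([0.1, 0.2, 0.3, 0.4]), "ACGT")
        _, b = sample_proportional_pair(
            pi, ProportionalModelConfig(math.inf), n, seed=5
        )
        for ch, p in zip("ACGT", pi.probabilities):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(b.count(ch) / n - p) <= 3 * se

    def test_negative_mu_t_rejected(self):
        with pytest.raises(InputError):
            ProportionalModelConfig(-0.1)


class TestSampleNullScores:
    def test_score_count_bookkeeping(self):
        pi = FrequencyVector(np.full(4, 0.25), "ACGT", total_count=100)
        vectors = resample_frequency_vectors(pi, n_boot=5, n_delete_half=4, seed=2)
        nd = sample_null_scores(vectors, load_matrix("NUC_MATCH"), w=6,
                                scores_per_resample=7, seed=2)
        assert nd.n_scores == 5 * 4 * 7

    def test_match_scores_are_match_counts(self):
        nd = sample_null_scores([uniform_frequencies("ACGT")],
                                load_matrix("NUC_MATCH"), w=6,
                                scores_per_resample=5000, seed=4)
        assert np.array_equal(nd.scores, nd.scores.astype(int))
        assert nd.scores.min() >= 0 and nd.scores.max() <= 6

    def test_determinism_bit_identical(self):
        vecs = [uniform_frequencies("ARNDCQEGHILKMFPSTWYV")]
        m = load_matrix("BLOSUM62")
        a = sample_null_scores(vecs, m, w=6, scores_per_resample=1000, seed=11)
        b = sample_null_scores(vecs, m, w=6, scores_per_resample=1000, seed=11)
        assert np.array_equal(a.scores, b.scores)

    def test_sorted_ascending(self):
        nd = sample_null_scores([uniform_frequencies("ACGT")],
                                load_matrix("NUC_MATCH"), w=4,
                                scores_per_resample=100, seed=0)
        assert (np.diff(nd.scores) >= 0).all()


class TestComputeCutoff:
    def test_degenerate_distribution(self):
        nd = NullDistribution("MATCH", 6, np.full(50, 7.0))
        assert compute_cutoff(nd, 0.95).c == 7

    def test_sort_and_index_oracle(self):
        nd = NullDistribution("MATCH", 6, np.arange(1000, dtype=float))
        assert compute_cutoff(nd, 0.95).c == 949

    def test_brute_force_quantile_property(self):
        """c is the smallest score whose empirical CDF reaches alpha."""
        rng = np.random.default_rng(8)
        scores = rng.integers(0, 30, size=777).astype(float)
        nd = NullDistribution("MATCH", 6, scores)
        for alpha in (0.5, 0.9, 0.95, 0.99):
            c = compute_cutoff(nd, alpha).c
            cdf = lambda x: np.mean(nd.scores <= x)
            assert cdf(c) >= alpha
            smaller = nd.scores[nd.scores < c]
            if len(smaller):
                assert cdf(smaller.max()) < alpha

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        nd = NullDistribution("MATCH", 6, rng.normal(size=5000))
        cuts = [compute_cutoff(nd, a).c for a in (0.5, 0.8, 0.9, 0.95, 0.99)]
        assert cuts == sorted(cuts)

    def test_exact_binomial_oracle(self):
        """MATCH / uniform 4-letter null: c(0.95) = 3 by the Binomial(6, 1/4) CDF."""
        assert stats.binom.cdf(2, 6, 0.25) < 0.95 <= stats.binom.cdf(3, 6, 0.25)
        nd = sample_null_scores([uniform_frequencies("ACGT")],
                                load_matrix("NUC_MATCH"), w=6,
                                scores_per_resample=100_000, seed=12)
        assert compute_cutoff(nd, 0.95).c == 3

    def test_invalid_inputs(self):
        nd = NullDistribution("MATCH", 6, np.array([1.0]))
        with pytest.raises(InputError):
            compute_cutoff(nd, 1.0)
        with pytest.raises(InputError):
            compute_cutoff(NullDistribution("MATCH", 6, np.array([])), 0.95)


class TestPersistence:
    def test_round_trip(self, tmp_path):
        nd = sample_null_scores([uniform_frequencies("ACGT")],
                                load_matrix("NUC_MATCH"), w=5,
                                scores_per_resample=200, seed=6)
        path = tmp_path / "null.tsv"
        save_null_distribution(nd, path)
        back = load_null_distribution(path)
        assert back.matrix_name == nd.matrix_name and back.w == nd.w
        assert np.array_equal(back.scores, nd.scores)
        assert back.seed == nd.seed
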