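"""Build a null distribution of randomly similar window scores.

With identity (MATCH) scoring and uniform nucleotide frequencies the null
is exactly Binomial(w, 1/4) — the number of chance matches in a window —
so the empirical cutoff can be checked against the analytic quantile.
"""

from scipy import stats

from alimask import (
    compute_cutoff,
    load_matrix,
    sample_null_scores,
    uniform_frequencies,
)

pi = uniform_frequencies("ACGT")
matrix = load_matrix("NUC_MATCH")
nd = sample_null_scores([pi], matrix, w=6, scores_per_resample=100_000, seed=1)
cut = compute_cutoff(nd, alpha=0.95)

print(f"{nd.n_scores:,} null window scores, w = {nd.w}")
print(f"empirical cutoff c(0.95) = {cut.c:.0f}")
print(f"analytic check: P(X <= 2) = {stats.binom.cdf(2, 6, 0.25):.4f} < 0.95"
      f" <= P(X <= 3) = {stats.binom.cdf(3, 6, 0.25):.4f}  ->  c = 3")
# A window must score STRICTLY above c to count as non-random, so with
# MATCH scoring two unrelated nucleotide sequences need >= 4 matches in a
# 6-column window before the profiler calls the window signal.
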