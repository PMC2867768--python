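"""Profile a simulated amino-acid alignment and score the mask against truth.

Builds a 10-sequence alignment with a 40-column conserved core and a
20-column randomized flank, runs the sliding-window profiler with its
defaults (BLOSUM62, w=6, alpha=0.95), and compares the resulting mask with
the known column labels.
"""

from alimask import confusion_vs_truth, profile_alignment, simulate_alignment

sim = simulate_alignment(seed=42)
aln = sim.alignment
print(f"simulated alignment: {aln.n_rows} rows x {aln.length} columns "
      f"(40 conserved + 20 randomized)")

result = profile_alignment(aln, seed=42)
mask = result.mask
sens, spec = confusion_vs_truth(mask, sim.truth)

print(f"null cutoff c(0.95) = {result.cutoff.c:.1f} "
      f"from {result.null_meta['n_null_scores']:,} null scores")
print(f"retained {mask.n_retained}/{aln.length} columns")
print(f"sensitivity (randomized columns excluded): {sens:.2f}")
print(f"specificity (conserved columns retained):  {spec:.2f}")
# Values near 1.0 mean the profiler separates homology signal from
# compositional noise on this alignment; the few misses sit at the
# conserved/randomized boundary where windows straddle both.
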