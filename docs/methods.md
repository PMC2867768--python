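# Methods

## The problem

Multiple sequence alignments of divergent loci contain sections whose
apparent similarity is explained by residue composition alone. Such
"randomly similar" sections — typically indel-riddled, saturated or
mis-aligned stretches — degrade tree reconstruction. `alimask` scores
every alignment column for randomness and produces a retained/excluded
mask, via a parametric sliding-window test and, as a comparator, a
rule-based conserved-block filter.

## Sliding-window randomness profiling

### Window score

For a sequence pair and window width `w` (default 6), the score of the
window starting at column `k` is the sum of per-site scores under a
substitution matrix `Q`:

* residue–residue: the matrix entry `Q_ab`;
* gap or ambiguity code vs residue: the matrix's stop-codon (`*`) score
  for that residue — BLOSUM62 gives −4 for any residue;
* gap/ambiguity vs gap/ambiguity: `c/w`, where `c` is the null cutoff.
  A window of matching indels therefore scores exactly `c`, and because a
  window call requires `S(k) > c` *strictly*, gap-only stretches are
  always called random. Ambiguity codes (N/R/Y/… on nucleotide level,
  X/B/Z/J on amino-acid level) are treated like gaps at both levels.

Matrices: `BLOSUM62` (default for amino acids), `PAM250`, `PAM500` and
identity `MATCH`/`NUC_MATCH` (match 1, mismatch 0, indel row 0). The
standard NCBI integer half-bit tables shipped with `biotite` are used,
restricted to the 20 amino acids, with the `*` row as the indel score.
Scores are kept as floats throughout because `c/w` is fractional.

### Null distribution: complex bootstrap + Proportional model

The null asks: how large do window scores get between sequences that
share composition but no ancestry?

1. Residue frequencies π and the total residue count `N` are collected
   from all unambiguous residues of the alignment.
2. Complex bootstrap: `n_boot` (100) multinomial redraws of the `N`
   observed residues; from each, `n_delete_half` (100) subsamples of
   `⌊N/2⌋` residues drawn without replacement (multivariate
   hypergeometric). The 10,000 renormalized count vectors spread the null
   over the sampling uncertainty of π. The bootstrap mechanics
   (multinomial redraw + hypergeometric delete-half) are the standard
   readings of those terms; the method's description names but does not
   define them.
3. From each frequency vector, `scores_per_resample` (100) pairs of
   length-`w` sequences are generated and scored, giving 1,000,000 null
   scores at the defaults. Generation follows the Proportional model, a
   Poisson-type amino-acid model with stationary frequencies π:

       P_ij(t) = exp(-μt) δ_ij + π_j (1 - exp(-μt)).

   The first sequence is i.i.d. from π; the second copies each site with
   probability `exp(-μt)` and is otherwise redrawn from π. Null
   generation defaults to `μt = ∞`, i.e. both sequences independent given
   π: randomly similar sequences carry no phylogenetic signal, and any
   finite `μt` would only shift the null toward higher similarity. The
   parameter is exposed for experimentation.

The cutoff `c(α)` (α = 0.95) is the smallest null score whose empirical
CDF reaches α — the `⌈αn⌉`-th smallest of the sorted scores. Ties at `c`
count toward the null.

With identity scoring and fixed π the null is analytically
Binomial(`w`, Σπ²); the test suite and acceptance script use this as an
exact oracle (uniform nucleotide frequencies: Binomial(6, ¼), giving
c(0.95) = 3).

### Profiling and aggregation

`max_pairs` (2,000) sequence pairs are drawn uniformly without
replacement (all pairs when fewer exist). For each pair the window slides
in steps of one column; each placement is called +1 if `S(k) > c`, else
−1. A column's pair score is the mean call over the windows covering it
(terminal columns are covered by as few as one window and averaged over
their actual coverage); the consensus score is the mean over pairs, and a
column is retained iff its consensus is strictly positive — a tie looks
random. This per-position aggregation rule is the package's own
documented convention for turning window calls into a column mask; the
sliding-window literature it follows does not fix one canonical rule.

Amino-acid mode builds **one global null** per run from alignment-wide
frequencies. Nucleotide mode rebuilds the null **per pair** from the
pooled base composition of the two sequences, adapting the cutoff to
compositional heterogeneity among sequences; adaptation *along* sequences
is out of scope. Because a per-pair null multiplies the work by the
number of pairs, the nucleotide bootstrap is lighter by default
(10 × 10 × 100 = 10,000 scores per pair); the 0.95-quantile of 10,000
scores is stable to within the score discretization, and the global
100 × 100 × 100 sizes remain available through the API.

All randomness flows from one user seed, fanned out to pair selection,
bootstrap and null generation through `numpy` seed sequences; identical
configuration and seed reproduce bit-identical distributions, profiles
and masks.

## Rule-based block filter

The comparator implements the classic conserved-block rule set in a
deliberately simplified, fully configurable form:

1. a column is *conserved* when strictly more than `conserved_threshold`
   (0.5, i.e. "half plus one") of the rows carry the modal non-gap
   residue, *highly conserved* at ≥ `highly_conserved_threshold` (0.85);
   gaps and ambiguity codes never count toward the modal residue;
2. columns failing the gap rule are demoted to non-conserved. Gap modes:
   `none` (no gaps), `half` (fewer than 50% of rows gapped — exactly half
   fails), `all` (gaps ignored);
3. runs of more than `max_nonconserved_run` (8) contiguous non-conserved
   columns are rejected;
4. the remaining segments are trimmed inward to highly conserved flanks
   and must reach `min_block_length` (10).

Relaxing the gap mode can only flip columns from non-conserved to
conserved, shrink rejected runs and extend segments, so the retained sets
nest: none ⊆ half ⊆ all. This monotonicity is verified over simulated
alignments rather than assumed. Bit-compatibility with the original
GBLOCKS program is a non-goal; defaults mirror its conservative
behaviour (large, gap-free, well-conserved blocks survive).

## Synthetic alignments

`simulate_alignment` builds the validation data: conserved blocks evolve
on a star tree (one ancestor from π, each row evolved independently per
site under the Proportional model at `divergence_mu_t`), randomized
blocks are i.i.d. from π, and gaps are injected uniformly at
`gap_fraction` — by default only into randomized blocks so the
column-level ground truth stays binary (`gaps_in_conserved=True` for
stress tests). A star tree rather than a bifurcating one keeps the truth
unambiguous while creating the signal/noise contrast the masker must
detect.

Defaults (the study conditions of the validation suite): 10 rows, blocks
(conserved 40, randomized 20), uniform π, `divergence_mu_t = 0.3`
(≈ 75% expected pairwise identity in conserved blocks), `gap_fraction
= 0.1`. Masks are scored as sensitivity = randomized columns excluded /
randomized columns, specificity = conserved columns retained / conserved
columns.

What the simulator does **not** emulate: insertion/deletion evolution
along a tree (gaps are i.i.d. noise, not indel histories), site-rate
heterogeneity, codon structure, non-stationary composition within a
sequence, and real aligner artifacts. Passing the validation suite shows
the method separates compositional noise from star-tree signal at these
settings; it does not certify performance on any particular empirical
locus.

## Numerical choices and edge cases

* Cutoff convention: smallest score with CDF ≥ α; window calls use strict
  `>`; consensus retention uses strict `> 0`.
* Null sampling is vectorized (inverse-CDF categorical draws in chunks of
  1,000 frequency vectors); 1,000,000 scores take about two seconds on
  one CPU.
* Problem sizes in tests and the acceptance script — 20 simulation seeds
  for parameter recovery, 50 alignments for gap-mode monotonicity, 10⁵
  draws for the binomial oracle — were chosen so the whole suite
  completes in well under a minute per component while keeping Monte
  Carlo error far from the asserted margins (3 standard errors where a
  tolerance is needed).
* A mask that excludes every column yields a valid 0-length alignment
  plus an explicit warning; exclusion ranges are written 1-based
  inclusive and re-parse to exactly the excluded set.
* Degenerate inputs rejected with typed errors: < 2 sequences, ragged
  rows, unknown characters, window wider than the alignment, empty null
  distribution, α outside (0, 1), frequency samples of fewer than 2
  residues.

## Known limitations

* The Proportional model ignores rate heterogeneity and any structure in
  the substitution process beyond stationary frequencies; the window
  test inherits this simplicity (by design — the null must be cheap to
  resample a million times).
* Nucleotide mode adapts composition per pair, not along sequences.
* The block filter is a comparator, not a GBLOCKS replacement: exact
  flank-trimming interactions of the original are not reproduced.
* Consensus aggregation weights all sampled pairs equally; closely
  related pairs are not down-weighted.
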