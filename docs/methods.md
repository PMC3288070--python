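# Methods

## Spectra and matching

A compositional spectrum is the vector of imperfect-match frequencies of
a fixed word set along a sequence.  Windows slide one position per step;
a window of length *L* matches a word if their Hamming distance is at
most *r*.  Windows containing any non-ACGT letter are skipped and the
window count *M* is reduced accordingly; this avoids fabricating matches
inside assembly gaps and hard-masked runs (soft-masked lowercase letters
are scored normally).  A window inside the Hamming ball of several words
counts once for each of them: the per-word counts m(w<sub>i</sub>) are
defined independently per word.

Matching is implemented by a precomputed table over the 4<sup>L</sup>
word space mapping every L-mer code (2 bits per letter) to the indices
of all vocabulary words within distance *r* (a CSR layout; guarded to
L ≤ 13).  The table is an optimisation only: the test suite pins it to a
naive per-window scan on random sequences, with and without ambiguous
letters.

## Vocabulary generation

Vocabularies are grown greedily from a random seed L-mer: candidates are
examined in a fixed order and kept iff they differ from every kept word
in at least `min_dist` positions; the scan stops when it returns to the
seed.  The default candidate order visits seed (+) v, where v runs
through all L-mers alphabetically and (+) is letter-wise GF(4) addition
(XOR of the 2-bit letter codes).  Because GF(4) translation preserves
Hamming distances, this is exactly the greedy lexicode grown from
AAA...A and translated onto the seed.  Consequences: the set size is
provably identical for every seed; at L = 10, `min_dist` = 6 it is
exactly 256 = 4⁴ words (the lexicode is linear), and differently seeded
sets are distance-isometric translates of one another, which is what
makes independently seeded probe sets interchangeable in practice.

A literal alphabetical scan of the words themselves (wrapping from
TTT...T to AAA...A) is kept as `scan="cyclic"`.  It is *not*
distance-compatible with integer order: its size depends on the seed and
is typically ~100 words at (10, 6).  It is retained for comparison, not
used by default.

With `min_dist` = 6 and r = 3, two balls can intersect only when the
word distance is exactly 6 = 3 + 3, so a 10-mer can match at most two
words; multiplicity is counted honestly rather than assumed to be ≤ 1.
Coverage is reported both as the match multiset size n·μ (always exact)
and as the number of distinct covered L-mers (by enumeration), since the
two differ whenever balls overlap.

## Distance

d = (1 − r<sub>s</sub>)/2, the unique affine map sending rank-identical
spectra to 0 and rank-reversed spectra to 1.  Because counts are
integers, ties are routine; r<sub>s</sub> is computed as the
product-moment correlation of average (mid) ranks, which reduces to the
classical 1 − 6Σδ²/(n(n²−1)) formula when ties are absent.  A constant
counts vector (possible on very short inputs) raises an explicit error
rather than returning NaN.  The reported distance minimises over the
four strand/reverse-complement orientation pairings; the spread among
the four terms is itself a strand-asymmetry signal.

## Heterogeneity

Sequences are segmented into non-overlapping windows (default 100 kb,
trailing remainder discarded; windows with > 50 % ambiguous letters are
excluded).  Defaults follow the standard analysis conditions: ΔGC
threshold 0.02 for H<sub>o</sub> (pairs with larger GC difference are
excluded so composition does not leak into the organizational score), GC
bin width 0.01 with half-open bins (lower edge inclusive), and a minimum
of 10 segments per surviving GC bin.  H<sub>c</sub> uses the absolute GC
difference, the only meaningful choice for unordered pairs.  When no
pair qualifies for H<sub>o</sub> the score is reported as NaN with an
explicit flag rather than silently dropped.

When the number of segment pairs exceeds 2×10⁶, a seeded uniform sample
of 10⁶ pairs is scored instead (drawn with replacement — at these sizes
duplicate pairs are negligible and the estimator stays uniform), and the
sampling error of the median is estimated by bootstrap over the sampled
distances.  All-pairs and sampled runs are compared directly in the
tests.

Whole-genome versus inter-chromosomal comparison pools all segments for
the former and takes the median over chromosome pairs of cross-pair
scores for the latter.  Fraction concatenations (coding / repeat / GDM)
are segmented exactly like plain sequences; windows may span
concatenation junctions, matching a concatenate-then-segment pipeline.
Fraction precedence is coding > repeat > GDM, so a repeat overlapping an
annotated gene is counted as coding.  Both genome-wide and
per-chromosome concatenation scopes are available (the CLI default is
genome-wide).

## Reshuffling null and combinatorics

The default shuffle is an unbiased Fisher–Yates permutation.  The
sweep-and-swap variant (each position i swapped with a uniformly random
position) is kept as `method="paper_swap"`: it preserves composition
but its permutation distribution is not uniform, which is why it is not
the default.  One shuffle replicate per segment is used; the comparison
statistic is a median over many segment pairs, so replicate averaging
adds little.

Under within-strand parity (%A = %T, %C = %G), the number of distinct
sequences with n₁ A+T and n₂ C+G letters is the exact multinomial
N = n!/((n₁/2)!²(n₂/2)!²), maximal at n₁ = n₂.  Its growth rate
(1/n)log₂N converges to the entropy of (α/2, α/2, (1−α)/2, (1−α)/2)
where α is GC content — 2 bits/letter at α = 0.5, 1 bit at the
endpoints.  The entropy form is validated against the exact big-integer
count at n = 2000 (agreement < 0.01 bits/letter).

## Synthetic data

The generator emulates a genome as a mosaic of "CS-states": each state
has a GC target (letters drawn with within-strand parity, A = T =
(1−GC)/2, C = G = GC/2) and a stickiness `bias` — with probability
`bias` a position copies its predecessor, otherwise it is drawn iid.
This is a first-order Markov chain whose stationary composition equals
the target (per-block empirical GC is within ±0.02 at 100 kb), and
whose letter-run structure gives all segments of a state a shared
spectral signature that reshuffling destroys.  Chromosomes are laid out
as sequences of fixed-length state blocks; an optional annotation plan
emits periodic synthetic gene/repeat intervals so the fraction pipeline
can be exercised end to end.  All randomness flows through one seeded
generator.

What the generator does *not* emulate: real repeat families and their
homology structure, CpG suppression and codon structure, long-range
correlations beyond first order, and assembly artefacts.  Passing tests
therefore demonstrate that the statistics behave as designed under
controlled composition/organization mixtures — not that any particular
biological value is reproduced.  Genome-scale results (vertebrate
tables and figures) require full assemblies and annotation downloads
and are out of scope here; the pipeline supports them but nothing in
the tests depends on them.

## Problem sizes and numerical choices

Test fixtures use 4–20 kb segments for unit-level checks and the
standard 100-kb window where the claim is about the standard conditions
(the vocabulary-interchangeability bound of 0.005 in particular: at
windows much below 100 kb, vocabulary-specific counting noise in the
spectra exceeds that bound, so the fixture uses 24 segments of 100 kb).
The random-composition baseline uses 200 segments of 100 kb (19 900
pairs), where the median oriented distance is 0.5 within ±0.01.
Exhaustive oracles (ball enumeration, distinct-sequence counting,
greedy-scan hand execution) run at L ≤ 5 and n ≤ 8, where enumeration
is exact.  The greedy scan and lookup construction are numba kernels
with early-exit distance tests; everything they produce is contract-
checked against naive scans.

## Known limitations

* Distinct-coverage accounting and lookup tables require L ≤ 13
  (4^L-sized tables); longer words fall back to per-window comparison
  for counting but cannot report distinct coverage.
* The Spearman distance is undefined for constant spectra, so extremely
  short or low-complexity segments should be filtered before scoring.
* GFF3 span extraction uses columns 1/3/4/5 only; feature-type
  filtering is by the `type` column, not by attribute parsing.
* The paper_swap shuffle is intentionally non-uniform; use the default
  for statistical work.
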