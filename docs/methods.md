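# Methods

## Problem

A sketch of a string is an ordered subsequence of its k-mer sequence, each
element carrying its 0-based source offset. Fix a score function `sc` over
sketch pairs and a threshold rule `thr(|p|)`. For a pattern sketch *p* (the
read) and text sketch *t* (the reference), a window *t[a, b]* is a **final
mapping** when (1) `sc(p, t[a,b]) >= thr(|p|)`, (2) it is left- and
right-reasonable (`occ(t[a], t[a,b]) <= occ(t[a], p)` and the mirrored
condition at *b* — the window starts and ends with k-mers that genuinely
match the pattern), and (3) it is maximal (no window containing it has a
*strictly* greater score). The mapper reports all final mappings; equal-score
nested or overlapping windows are deliberately all reported, because only a
strictly better containing window is evidence that a hit is a fragment of
something larger.

All scores ignore k-mer order. With `x_min/x_max/x_diff` the per-k-mer
min/max/absolute difference of occurrence counts, the identity
`|s| + |p| = Σ(2·x_min + x_diff)` converts freely between the supported
forms; the two scores used are the weighted Jaccard `Σx_min / Σx_max` and the
linear score `Σ(x_min − w·x_diff)`, `w > 0`. `w` trades the reward of a
shared occurrence against the penalty of a non-shared one; `w = 1` (the
default) weights them equally.

### Threshold conversions

Any weighted-Jaccard cutoff is reproduced exactly by a linear scheme:
`t ∈ (0,1) → (w = t/(1−t), cutoff 0)`; `t = 1` accepts exactly permutations
of *p*, which are exactly the windows attaining `sc_l = |p|`, so the cutoff
is `|p|`; `t > 1` is unattainable and maps to cutoff `|p|+1`. At `t = 0` the
Jaccard scheme accepts *every* window, which no positive-weight finite-cutoff
linear scheme does; the conversion therefore returns cutoff −∞ there. Note
these conversions preserve the *accepted set*, not the score ordering:
maximality compares raw scores, and the two scores can order nested windows
differently, so final sets under a Jaccard scheme and its converted linear
scheme may differ legitimately. The four re-parameterized family members
(weights on `x_min`, both terms, `x_max`, or `|s|`) are affine in `sc_l` with
positive scale and a `|p|`-only offset, hence fully interchangeable.

## Exact algorithm

Only windows whose endpoints lie on `L` — the positions of *t* carrying
pattern k-mers, `ℓ = |L|` — can be reasonable. The DP matrix
`S(i,j) = Σ_x min(occ(x,p), occ(x, t[L[i],L[j]]))` is filled right to left:
the last column bottom-up (incrementing a running count table `T_cnt` and
adding 1 exactly when the entering k-mer still fits the pattern's budget),
every other column from its right neighbour by subtracting 1 exactly when
the leaving k-mer `t[L[j+1]]` fit the budget of the wider window. The case
test runs in O(1) via `occ(x, t[L[i],L[j+1]]) = c2 − c1`, where `c2` is the
prefix count maintained in `T_cnt` and `c1` accumulates occurrences of the
leaving k-mer above row *i*. Scores are derived from the integer `S(i,j)` at
read-out; the window length used is `L[j] − L[i] + 1` in text-sketch
positions, counting interleaved non-pattern k-mers, since the problem scores
the full subsequence `t[a,b]`. Two columns are live at any time; the column
scan-out runs as each column is completed, so memory is O(ℓ) beyond the
output. Total time O(|t| + |p| + ℓ²).

The per-column scan decides the three conditions:

- **right-reasonability** via `i*`, the smallest right-reasonable row of the
  column. The subtract-1 case of the recurrence is taken exactly at the
  right-reasonable cells of the column being left, so `i*` of column *j+1*
  falls out of the advance to column *j* (the last column computes its own
  during initialization, and a diagonal cell is always reasonable).
- **left-reasonability** via `S(i,j) = S(i+1,j) + 1` (the diagonal is always
  reasonable).
- **maximality** against a per-start-row prefix maximum over *all* DP cells
  traversed so far. The traversal order (columns right to left, rows top to
  bottom) visits every cell containing the current window first, and
  trimming non-pattern k-mers off any interval's ends can only raise its
  score, so the best containing cell dominates the best containing interval
  of any kind — including containing windows that are themselves unreasonable
  or below threshold, which a comparison against previously *reported*
  mappings alone would miss. Suppression is strict (`>`), so equal-score
  nested windows are all emitted. Per start row, the latest final mapping is
  buffered and an earlier one at the same start is emitted as soon as it is
  superseded, keeping the live output state O(ℓ).

Two engines produce identical column streams: scalar reference operations
written cell-by-cell against the recurrence, and a vectorized engine
(integer-recoded k-mers, numpy column updates) used by `find_mappings`.
A brute-force solver enumerates all O(|t|²) windows, checks reasonability
directly and quantifies maximality over all containing windows; the test
suite holds the streamed output equal to it on hundreds of randomized
instances under both scores, and holds the two engines' columns equal.

### Numerical choices

DP cell values and shared counts are exact integers; scores are computed
from them in floating point by one shared formula in both the mapper and the
brute-force solver, so cross-checks compare bitwise-identical floats.
Threshold acceptance uses `score >= thr − 1e-9` (the epsilon only matters for
fractional weights or Jaccard scores; integer-valued linear comparisons are
unaffected); maximality suppression uses exact strict `>`. Minimizer window
ties break to the leftmost position; a sequence with fewer k-mers than the
window yields an empty minimizer sketch. FracMinHash membership is
`h(x) <= q` with `h` a seeded splitmix64-style mixer over the 2-bit-packed
k-mer, mapped to [0,1] (a keyed blake2b digest covers non-ACGT tokens);
non-ACGT characters break k-mer runs. Multi-record references are processed
per record; windows never span records.

## Mutation model and read simulation

Each source position independently draws an action (substitute with
probability `p_sub`, delete with `p_del`, else unchanged) and an insertion
length from a geometric distribution on {0, 1, 2, ...} with mean `p_ins`
(`P(0) = 1/(1+p_ins)`); the output interleaves the insertions before each
surviving position, with substitutions drawn uniformly from the three other
bases. This geometric convention is the one under which a k-mer occurrence
survives untouched with probability
`α = (1−p_del−p_sub)^k / (1+p_ins)^(k−1)` (all k actions unchanged, all k−1
internal insertion slots empty). The model is stated on circular strings so
every position has an insertion slot before it; linearized, insertions
"before position 0" sit at the front and no extra slot exists after the last
position. Read simulation draws gamma-distributed lengths (defaults: mean
9000 bp, sd 7000 bp, a HiFi-like profile), uniform starts, uniform strands,
and a total error rate (default 0.2%) split sub:ins:del = 6:50:54; true
origins are encoded in the FASTA headers.

## Threshold calibration

Analytical route (FracMinHash only): `E[sc_l(s, s'; w)] =
n_kmers · q · (α + w(2α − 2 + p_del − p_ins))`. `n_kmers` is the k-mer count
of the *un-sketched* string — n for a circular string of length n — and the
factor q is the expected sketch fraction; the parameter is exposed
explicitly as `n_kmers` to avoid the ambiguity of writing |s| for both.

Simulation route (any sketch): for each of several lengths, draw random
sequences, mutate at the target divergence, sketch both (a fresh hash seed
per replicate — the expectation being estimated averages over the hash
function, and with a single fixed hash the realized sampling fraction of the
finite k-mer universe is q only to ~2·10⁻⁴, which a few thousand replicates
resolve), score the pairs, and take the lower empirical quantile at index
`ceil((1−confidence)·reps)` — the largest cutoff retaining at least the
requested fraction of true mappings. Thresholds are keyed by read length in
bp (what a mapper knows per read) and interpolated piecewise-linearly
between knots, clamped outside; the mean pattern-sketch size per knot is
recorded for transparency. In practice one calibrates at a divergence
*above* the expected sequencing error (the shipped examples use 2% for
0.5%-error reads) so that diverged homologous copies still pass; calibrating
exactly at the error rate makes the quantile a knife's edge for true
origins. Note two small mismatches between calibration and mapping remain by
design: calibration scores standalone sequence pairs, whereas a mapped
read's flanks select slightly different minimizers inside the reference
context, and interpolation is linear between knots; both push mapped scores
slightly below calibrated cutoffs, which the lenient calibration divergence
absorbs.

### Accuracy of the closed form

The expectation formula assumes *mutation-distinctness*: mutations never
recreate a k-mer of the original string. The model itself violates this:
deleting a base next to an equal base, or inserting a base equal to one of
its neighbours, reproduces an original k-mer (probability ≈ 1/2 per
single-base indel). At the validation conditions used here (distinct-11-mer
circular strings of 2000 bp, q = 0.2, `p_sub = p_del = 0.003`,
`p_ins = 0.002`) that is ≈ 6 recreation events per replicate, and the
Monte-Carlo mean exceeds the closed form by ≈ 1.2% (`scripts/acceptance.py`
reports the measured relative error). The suite therefore validates the
formula to Monte-Carlo precision in the substitution-only regime, where
recreations need ~4^−k coincidences, and bounds the full-indel discrepancy
at a few percent; a 3-standard-error equality test at 2000 replicates fails
against this structural bias, and one such check is retained, failing, in
`tests/test_acceptance.py` to document it. Distinct-k-mer inputs are
generated by backtracking construction (optionally over the circular wrap),
and the expected-score check enumerates k-mers circularly so end effects
vanish.

## What the synthetic data does and does not show

Synthetic references are i.i.d. uniform DNA (plus constructed diverged
duplications in the examples); they have no long tandem repeats, no biased
composition, no N runs, and mutation is homogeneous along the read. Passing
tests therefore establish algorithmic correctness — the streamed DP equals
the literal problem definition, scores and conversions are exact, the
calibration machinery matches its own model — not mapping accuracy on real
genomes. On real repetitive references the frequency filter (default: drop
minimizers occurring > 100 times in the reference sketch) bounds ℓ and hence
the quadratic work, at a known cost in sensitivity inside those regions.

## Problem sizes used by the shipped checks

Randomized equivalence suites use token sketches with |t| ≤ 60, |p| ≤ 15
over a 4-letter alphabet (hundreds of instances; the brute-force solver is
cubic-ish and is the bottleneck). Monte-Carlo checks use 2000 bp sequences
with k = 11, q = 0.2 and 300–2000 replicates. The end-to-end round trip maps
50 reads (mean 3 kb) against a 100 kb reference with k = 15, window 10 —
sizes chosen so the whole suite runs in well under a minute per file while
every estimate stays several standard errors away from its decision
boundary.

## Known limitations

- No base-level alignment, chaining, extension or MAPQ: output is sketch
  windows with scores.
- Syncmer sketches and homopolymer compression are not implemented; the
  minimizer implementation is standard winnowing, not bit-compatible with
  any specific external tool.
- The analytical threshold applies to FracMinHash only, gives an expectation
  without a variance, and inherits the distinctness-assumption bias above.
- Reverse-strand handling is at the pipeline level (map the read and its
  reverse complement against a canonical-k-mer reference sketch); the core
  algorithm itself is strand-agnostic.
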