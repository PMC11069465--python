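# sketchmap

Exact sketch-based **all-hits** long-read mapping.

Modern long-read mappers work on *sketches* — ordered subsequences of a
sequence's k-mers, such as minimizers or FracMinHash selections — and use
heuristics (anchoring, chaining) to propose mapping locations. That is fast,
but in references with ampliconic regions, segmental duplications or
multi-copy gene families, a read legitimately belongs to *several* places,
and a heuristic best-hit mapper silently drops some of them. `sketchmap`
solves the underlying problem exactly: given the sketch *t* of a reference
and the sketch *p* of a read, report **every** window *t[a, b]* that

1. scores at least a threshold, `sc(p, t[a,b]) >= thr(|p|)`;
2. is **left-** and **right-reasonable** — its first and last k-mers occur in
   the window no more often than in the pattern, i.e. the window starts and
   ends with a real match
   (`occ(t[a], t[a,b]) <= occ(t[a], p)`, same at *b*);
3. is **maximal** — no containing window scores strictly higher.

## Scores

Scores are order-free functions of the two k-mer multisets. With
`x_min = min(occ(x,p), occ(x,s))`, `x_max = max(...)`, `x_diff = x_max − x_min`:

- weighted Jaccard   `sc_j(s,p) = Σ x_min / Σ x_max`,
- linear score       `sc_l(s,p; w) = Σ (x_min − w·x_diff) = (1+2w)·Σ x_min − w(|s|+|p|)`, `w > 0`.

The linear score *strictly dominates* the weighted Jaccard: any Jaccard
cutoff `t < 1` is reproduced exactly by the linear scheme
`(w = t/(1−t), cutoff 0)`, while no Jaccard cutoff can reproduce every linear
separation (`sketchmap.jaccard_threshold_to_linear`). Four natural variants
re-weighting `x_min`, `x_diff`, `x_max` or `|s|` are all affine transforms of
`sc_l` (`sketchmap.variant_to_linear`) and hence equivalent.

## Algorithm

Reasonable windows must start and end at positions of *t* carrying pattern
k-mers; with `L` the list of those positions and `ℓ = |L|`, a dynamic program
fills the matrix `S(i,j) = Σ_x min(occ(x,p), occ(x, t[L[i],L[j]]))` right to
left via

```
S(i,j) = S(i,j+1) − [ occ(t[L[j+1]], t[L[i],L[j+1]]) ≤ occ(t[L[j+1]], p) ]
```

holding only two columns in memory; either score is derived from the integer
`S(i,j)` in O(1) at read-out. A streaming scan decides reasonability and
maximality on the fly. Total cost `O(|t| + |p| + ℓ²)` time — quadratic only
in the number of shared sketch positions. A brute-force reference solver
(`sketchmap.oracle`) implements the problem definition literally and backs
the algorithm's equivalence tests.

## Thresholds

Two calibrations are built in (`sketchmap.calibrate`):

- **analytical** (FracMinHash, sampling rate *q*): under a per-base mutation
  model (substitutions `p_sub`, deletions `p_del`, geometric insertions with
  mean `p_ins`), `E[sc_l] = n·q·(α + w(2α − 2 + p_del − p_ins))` with
  `α = (1−p_del−p_sub)^k / (1+p_ins)^(k−1)`;
- **simulation-based** (any sketch): score mutated sequence pairs at several
  lengths, take a lower empirical quantile per length so that a chosen
  fraction of true mappings passes, and interpolate thresholds over read
  length.

## Worked example

`examples/map_reads.py` builds a 54 kb reference containing a second,
1%-diverged copy of one 4 kb region, simulates reads at 0.5% error, and maps
them (k = 15, minimizer window 10, linear score w = 1):

```
reference: 53994 bp, 9734 minimizers after filtering

  read           origin  mappings (ref span @ score)
 read0      32776-34764  32778-34758 @ 262
 read1      49530-51914  49532-51912 @ 333
 read2      49933-52502  49938-52493 @ 349
 read3      42194-44611  42197-44609 @ 314
   dup      11000-13500  11005-13496 @ 451; 31003-33491 @ 270; ...
```

Each line is a read's true origin followed by every reported window (0-based
half-open reference span and its linear score). Reads from unique sequence
map once, at their origin; the read drawn from the duplicated region is also
reported at the diverged copy, at a lower but above-threshold score — the
hits a best-hit mapper would drop. The other examples print the
counterexample behind the score-domination result (`examples/scores.py`),
sketch-size expectations (`examples/sketching.py`), and both threshold
calibrations (`examples/calibration.py`).

## Command line

```
sketchmap simulate-reads -r ref.fa -n 1000 --mean 9000 --sd 7000 --rate 0.002 -o reads.fa
sketchmap calibrate --lengths 1000,3000,6000,12000,24000 --div 0.01 \
                    --conf 0.7,0.8,0.9,0.95 --seed 1 -o thresholds.tsv
sketchmap map -r ref.fa -q reads.fa -k 15 --window 10 --max-occ 100 \
              --score linear --weight 1 --threshold thresholds.tsv -o out.tsv
```

`map` writes one TSV row per final mapping (read, reference span, strand,
shared k-mer count, score, threshold applied); `--paf` emits a minimal
PAF-like format instead.

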