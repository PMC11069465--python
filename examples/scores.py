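"""Compare the weighted Jaccard and linear sketch-similarity scores.

Both scores see a sketch as a multiset of k-mers: x_min shared
occurrences raise them, x_diff non-shared occurrences lower them. The
linear score sc_l(s, p; w) = sum(x_min - w * x_diff) strictly dominates
the weighted Jaccard: any Jaccard cutoff can be rewritten as a linear
scheme with identical acceptances, but not the other way round — shown
here on the counterexample family, where the two scores order a short
exact fragment and a padded superset differently.
"""

from sketchmap import (
    OccurrenceProfile,
    jaccard_threshold_to_linear,
    linear_score,
    variant_to_linear,
    weighted_jaccard,
)
from sketchmap.score import VariantScoreParams

prof = OccurrenceProfile.from_kmers

p = prof([f"k{i}" for i in range(4)])            # pattern: 4 distinct k-mers
s1 = prof(["k0"])                                # short exact fragment
s2 = prof([f"k{i}" for i in range(4)] + [f"junk{i}" for i in range(8)])

print("pattern p: 4 distinct k-mers; s1 = 1 of them; s2 = p + 8 junk k-mers")
print(f"weighted Jaccard: sc_j(s1)={weighted_jaccard(p, s1):.4f}  "
      f"sc_j(s2)={weighted_jaccard(p, s2):.4f}   (prefers the padded s2)")
print(f"linear (w=1):     sc_l(s1)={linear_score(p, s1, 1.0):+.1f}    "
      f"sc_l(s2)={linear_score(p, s2, 1.0):+.1f}     (prefers the exact s1)")
print("a linear cutoff of -3 accepts s1 but rejects s2; "
      "no Jaccard cutoff can do that.")

params, cutoff = jaccard_threshold_to_linear(0.5, p_len=4)
print(f"\nJaccard cutoff 0.5 == linear scheme w={params.w:g}, cutoff {cutoff:g} "
      "(identical acceptance set)")

lin, scale, offset = variant_to_linear(VariantScoreParams("D", (3.0, 1.0)))
print(f"score variant D(3,1) == {scale:g} * sc_l(.; w={lin.w:g}) + {offset(4):g} "
      "for |p|=4 — the whole family is affine in sc_l")
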