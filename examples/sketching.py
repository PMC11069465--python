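"""Build k-mer sketches of a DNA sequence.

Enumerates the k-mers of a small random sequence, then reduces them two
ways: a (w, k)-minimizer sketch (the minimum-hash k-mer of every window
of w consecutive k-mers) and a FracMinHash sketch (every k-mer whose
uniform hash is at most a sampling rate q). Both are ordered
subsequences of the k-mer sequence, the mapper's only view of the data.
"""

from sketchmap import (
    count_occurrences,
    enumerate_kmers,
    filter_high_frequency,
    fracminhash_sketch,
    minimizer_sketch,
    random_dna,
)

seq = random_dna(2000, seed=0)
ks = enumerate_kmers(seq, k=15)
print(f"sequence: {len(seq)} bp -> {len(ks)} overlapping 15-mers")

mini = minimizer_sketch(ks, w_min=10, seed=0)
print(f"minimizer sketch (w=10): {len(mini)} k-mers "
      f"(~2/(w+1) of positions = {2 * len(ks) / 11:.0f} expected)")

frac = fracminhash_sketch(ks, q=0.2, seed=0)
print(f"FracMinHash sketch (q=0.2): {len(frac)} k-mers "
      f"(n*q = {len(ks) * 0.2:.0f} expected)")

counts = count_occurrences(mini)
filtered = filter_high_frequency(mini, counts, max_occ=100)
print(f"after dropping k-mers occurring >100 times: {len(filtered)} k-mers "
      f"(random sequence, so nothing is that frequent)")
print("first three minimizers (kmer @ offset):",
      ", ".join(f"{x}@{o}" for x, o in zip(mini.kmers[:3], mini.offsets[:3])))
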