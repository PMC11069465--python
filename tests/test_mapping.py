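import numpy as np
import pytest

from sketchmap import (
    ScoringScheme,
    Sketch,
    brute_force_final_mappings,
    brute_force_shared_count,
    build_shared_positions,
    count_occurrences,
    find_mappings,
)
from sketchmap.mapping import (
    _columns_fast,
    _columns_reference,
    advance_column,
    init_last_column,
    score_from_count,
)


def stream_columns(t, p, engine=_columns_reference):
    p_counts = count_occurrences(p)
    L = build_shared_positions(t, p_counts).L
    return L, list(engine(t.kmers, L, p_counts))


class TestSharedPositions:
    def test_toy(self, toy_instance):
        t, p = toy_instance
        L = build_shared_positions(t, count_occurrences(p)).L
        assert L.tolist() == [0, 2, 3]

    def test_disjoint(self):
        t = Sketch.from_tokens(list("xyz"))
        p = Sketch.from_tokens(list("ab"))
        assert build_shared_positions(t, count_occurrences(p)).ell == 0

    def test_identical(self):
        t = Sketch.from_tokens(list("abcd"))
        assert build_shared_positions(t, count_occurrences(t)).L.tolist() == [0, 1, 2, 3]


class TestLastColumn:
    def test_toy_values(self, toy_instance):
        t, p = toy_instance
        p_counts = count_occurrences(p)
        L = build_shared_positions(t, p_counts).L
        col, T_cnt = init_last_column(t.kmers, L, p_counts)
        assert col.values.tolist() == [2, 2, 1]
        assert T_cnt == {"a": 2, "b": 1}

    def test_single_shared_position(self):
        t = Sketch.from_tokens(list("xax"))
        p = Sketch.from_tokens(list("a"))
        p_counts = count_occurrences(p)
        L = build_shared_positions(t, p_counts).L
        col, _ = init_last_column(t.kmers, L, p_counts)
        assert col.values.tolist() == [1]

    def test_identical_distinct_pattern(self):
        t = Sketch.from_tokens(list("abcde"))
        p_counts = count_occurrences(t)
        L = np.arange(5)
        col, _ = init_last_column(t.kmers, L, p_counts)
        assert col.values.tolist() == [5, 4, 3, 2, 1]


class TestAdvanceColumn:
    def test_toy_recurrence_steps(self, toy_instance):
        t, p = toy_instance
        p_counts = count_occurrences(p)
        L = build_shared_positions(t, p_counts).L
        col2, T_cnt = init_last_column(t.kmers, L, p_counts)
        col1, i_star2 = advance_column(col2, t.kmers, L, p_counts, T_cnt)
        # S(1,1) = S(1,2) - 1 (leaving 'a' fits the pattern budget);
        # S(0,1) = S(0,2) - 0 (occ(a, t[0,3]) = 2 exceeds occ(a, p) = 1)
        assert col1.values.tolist() == [2, 1]
        assert i_star2 == 1
        col0, i_star1 = advance_column(col1, t.kmers, L, p_counts, T_cnt)
        assert col0.values.tolist() == [1]
        assert i_star1 == 0

    def test_absent_leaving_kmer_carries_values(self):
        # leaving k-mer occurs more often in the window than in p for
        # every row -> all values carried unchanged
        t = Sketch.from_tokens(list("aabaa"))
        p = Sketch.from_tokens(list("ab"))
        p_counts = count_occurrences(p)
        L = build_shared_positions(t, p_counts).L  # all 5 positions
        col, T_cnt = init_last_column(t.kmers, L, p_counts)
        nxt, _ = advance_column(col, t.kmers, L, p_counts, T_cnt)
        # leaving 'a' at L[4]: occ(a, window) > 1 = occ(a, p) for rows 0..2
        assert nxt.values.tolist()[:3] == col.values.tolist()[:3]

    def test_matrix_matches_naive_counts(self, make_random_instance):
        """Every streamed S(i, j) equals the brute-force shared count of
        its window, for both engines."""
        rng = np.random.default_rng(20)
        for _ in range(25):
            t, p = make_random_instance(rng, max_t=40, max_p=10)
            p_counts = count_occurrences(p)
            if build_shared_positions(t, p_counts).ell == 0:
                continue
            for engine in (_columns_reference, _columns_fast):
                L, cols = stream_columns(t, p, engine)
                for col in cols:
                    for i in range(col.j + 1):
                        naive = brute_force_shared_count(
                            t, int(L[i]), int(L[col.j]), p_counts
                        )
                        assert col.values[i] == naive

    def test_engines_agree_exactly(self, make_random_instance):
        rng = np.random.default_rng(21)
        for _ in range(40):
            t, p = make_random_instance(rng)
            if build_shared_positions(t, count_occurrences(p)).ell == 0:
                continue
            L1, ref = stream_columns(t, p, _columns_reference)
            L2, fast = stream_columns(t, p, _columns_fast)
            assert len(ref) == len(fast)
            for a, b in zip(ref, fast):
                assert a.j == b.j and a.i_star == b.i_star
                assert np.array_equal(a.values, b.values)

    def test_monotone_column_steps(self, make_random_instance):
        """S grows by 0 or 1 when widening a window on either side."""
        rng = np.random.default_rng(22)
        for _ in range(20):
            t, p = make_random_instance(rng, max_t=40, max_p=10)
            if build_shared_positions(t, count_occurrences(p)).ell == 0:
                continue
            L, cols = stream_columns(t, p)
            for col in cols:
                diffs = np.diff(col.values[: col.j + 1])
                assert set(diffs.tolist()) <= {-1, 0}
            for right, left in zip(cols, cols[1:]):
                step = right.values[: left.j + 1] - left.values
                assert set(step.tolist()) <= {0, 1}


class TestScoreFromCount:
    def test_toy_linear_readout(self, toy_instance):
        t, p = toy_instance
        L = np.array([0, 2, 3])
        scheme = ScoringScheme(kind="linear", w=1)
        assert score_from_count(2, 1, 2, L, 2, scheme) == 2  # window t[2,3]
        assert score_from_count(2, 0, 2, L, 2, scheme) == 0  # window t[0,3]

    def test_toy_jaccard_readout(self):
        L = np.array([0, 2, 3])
        scheme = ScoringScheme(kind="jaccard")
        assert score_from_count(2, 1, 2, L, 2, scheme) == 1.0


class TestFindMappings:
    def test_toy_final_set(self, toy_instance):
        """The worked instance: t[2,3] (score 2) and t[0,2] (score 1) are
        final; the diagonal windows are dominated and t[0,3] is
        unreasonable."""
        t, p = toy_instance
        out = find_mappings(t, p, ScoringScheme(kind="linear", w=1, thr=0))
        assert [(m.a, m.b, m.score) for m in out] == [(0, 2, 1.0), (2, 3, 2.0)]

    def test_threshold_above_maximum_gives_nothing(self, toy_instance):
        t, p = toy_instance
        assert find_mappings(t, p, ScoringScheme(thr=99)) == []

    def test_permutation_recovered_at_tight_threshold(self):
        tokens = list("abcdefg")
        t = Sketch.from_tokens(tokens)
        p = Sketch.from_tokens(tokens)
        out = find_mappings(t, p, ScoringScheme(kind="linear", w=1, thr=len(tokens)))
        assert [(m.a, m.b) for m in out] == [(0, 6)]
        assert out[0].score == len(tokens)

    def test_empty_pattern_is_error(self):
        with pytest.raises(ValueError):
            find_mappings(Sketch.from_tokens("ab"), Sketch.from_tokens([]))

    def test_empty_text_or_no_shared(self):
        p = Sketch.from_tokens(list("ab"))
        assert find_mappings(Sketch.from_tokens([]), p) == []
        assert find_mappings(Sketch.from_tokens(list("xyz")), p) == []

    def test_base_coordinates_attached(self):
        from sketchmap import enumerate_kmers

        ks = enumerate_kmers("ACGTACGT", 3)
        t = Sketch(ks.kmers, ks.offsets, 3, record_id="ref")
        p = Sketch.from_tokens(["ACG", "CGT"], k=3)
        out = find_mappings(t, p, ScoringScheme(thr=1))
        assert out and out[0].ref_id == "ref"
        for m in out:
            assert m.end == int(t.offsets[m.b]) + 3
            assert m.start == int(t.offsets[m.a])

    @pytest.mark.parametrize("w", [0.5, 1, 2])
    def test_equivalence_with_oracle_linear(self, w, make_random_instance):
        rng = np.random.default_rng(int(w * 10))
        for _ in range(40):
            t, p = make_random_instance(rng, max_t=45, max_p=12)
            thr = float(rng.choice([-4, 0, 1, 2.5]))
            scheme = ScoringScheme(kind="linear", w=w, thr=thr)
            got = [m.key() for m in find_mappings(t, p, scheme)]
            want = [m.key() for m in brute_force_final_mappings(t, p, scheme)]
            assert got == want

    def test_equivalence_with_oracle_jaccard(self, make_random_instance):
        rng = np.random.default_rng(99)
        for _ in range(40):
            t, p = make_random_instance(rng, max_t=45, max_p=12)
            scheme = ScoringScheme(kind="jaccard", thr=float(rng.uniform(0, 1)))
            got = [m.key() for m in find_mappings(t, p, scheme)]
            want = [m.key() for m in brute_force_final_mappings(t, p, scheme)]
            assert got == want

    def test_emitted_mappings_are_reasonable_and_maximal(self, make_random_instance):
        """Soundness against the definition directly: occurrence bounds at
        both ends, and no containing window of strictly greater score."""
        rng = np.random.default_rng(30)
        checked = 0
        for _ in range(30):
            t, p = make_random_instance(rng, max_t=35, max_p=10)
            scheme = ScoringScheme(kind="linear", w=1, thr=0)
            p_counts = count_occurrences(p)
            for m in find_mappings(t, p, scheme):
                window = t.kmers[m.a : m.b + 1]
                assert window.count(t.kmers[m.a]) <= p_counts[t.kmers[m.a]]
                assert window.count(t.kmers[m.b]) <= p_counts[t.kmers[m.b]]
                for a2 in range(m.a + 1):
                    for b2 in range(m.b, len(t)):
                        cnt = brute_force_shared_count(t, a2, b2, p_counts)
                        sc = scheme.score_from_count(cnt, b2 - a2 + 1, len(p))
                        assert not sc > m.score + 1e-9
                checked += 1
        assert checked > 50
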