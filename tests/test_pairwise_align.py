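"""Alignment substrate: optimality, identity statistic, dot plots."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hervetools as h
from hervetools.pairwise_align import (
    DEFAULT_SCORING,
    ScoringScheme,
    coverage_fraction,
    divergence_pct,
    dotplot,
    global_align,
    percent_identity,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=8)


def brute_force_best_score(a, b, scheme):
    """Enumerate every global alignment; a gap run of length k costs
    open + (k-1)*extend.  Exponential: only for tiny sequences."""

    def score(cols):
        total = 0.0
        prev = None  # 'V' or 'H' gap state
        for x, y in cols:
            if x == "-" or y == "-":
                state = "V" if y == "-" else "H"
                total += scheme.gap_extend if state == prev else scheme.gap_open
                prev = state
            else:
                total += scheme.match if x == y else scheme.mismatch
                prev = None
        return total

    best = -np.inf

    def rec(i, j, cols):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score(cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best


class TestGlobalAlign:
    def test_identity_case(self):
        aln = global_align("ACGT", "ACGT")
        assert (aln.n_identical, aln.n_compared) == (4, 4)
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_single_deletion(self):
        aln = global_align("ACGT", "AGT")
        assert aln.aligned_a == "ACGT"
        assert aln.aligned_b.count("-") == 1
        assert (aln.n_identical, aln.n_compared) == (3, 3)
        assert aln.score == brute_force_best_score("ACGT", "AGT", DEFAULT_SCORING)

    def test_five_substitutions_in_hundred(self, rng):
        a = "".join(rng.choice(list("ACGT"), 100))
        b = list(a)
        for pos in rng.choice(100, 5, replace=False):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        aln = global_align(a, "".join(b))
        assert (aln.n_identical, aln.n_compared) == (95, 100)
        assert percent_identity(aln) == pytest.approx(95.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    @given(a=dna, b=dna)
    @settings(max_examples=100)
    def test_score_is_brute_force_optimum(self, a, b):
        aln = global_align(a, b)
        assert aln.score == pytest.approx(
            brute_force_best_score(a, b, DEFAULT_SCORING)
        )

    @given(a=dna, b=dna)
    def test_degapping_recovers_inputs(self, a, b):
        aln = global_align(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b

    def test_identity_symmetric_on_diverged_pairs(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 120))
            b = list(a)
            for pos in rng.choice(120, 12, replace=False):
                b[pos] = rng.choice([c for c in "ACGT" if c != b[pos]])
            # plus one small indel
            cut = int(rng.integers(10, 110))
            b = "".join(b[:cut] + b[cut + 3 :])
            pid_ab = percent_identity(global_align(a, b))
            pid_ba = percent_identity(global_align(b, a))
            assert pid_ab == pytest.approx(pid_ba)


class TestPercentIdentity:
    def test_gap_and_n_columns_excluded(self):
        # 200 columns: 10 gap columns, 180 matches among 190 compared
        a = "A" * 190 + "C" * 10
        row_a = "A" * 190 + "-" * 10
        row_b = "A" * 180 + "G" * 10 + "C" * 10
        aln = h.PairwiseAlignment(row_a, row_b, 0.0, 180, 190)
        assert percent_identity(aln) == pytest.approx(94.7, abs=0.05)

    def test_all_gap_overlap_rejected(self):
        aln = h.PairwiseAlignment("A-", "-A", 0.0, 0, 0)
        with pytest.raises(ValueError):
            percent_identity(aln)


class TestDivergence:
    def test_self_divergence_zero(self, rng):
        x = "".join(rng.choice(list("ACGT"), 200))
        assert divergence_pct(x, x) == 0.0

    def test_known_identity_complement(self):
        # identity 92.2% corresponds to divergence 7.8%
        a = "A" * 922 + "C" * 78
        b = "A" * 922 + "G" * 78
        assert divergence_pct(a, b) == pytest.approx(7.8)

    def test_exact_on_substitution_only_pairs(self, rng):
        L, s = 450, 9
        a = "".join(rng.choice(list("ACGT"), L))
        b = list(a)
        for pos in rng.choice(L, s, replace=False):
            b[pos] = rng.choice([c for c in "ACGT" if c != b[pos]])
        assert divergence_pct(a, "".join(b)) == pytest.approx(100 * s / L)

    def test_invariant_to_joint_reverse_complement(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 150))
            b = list(a)
            for pos in rng.choice(150, 10, replace=False):
                b[pos] = rng.choice([c for c in "ACGT" if c != b[pos]])
            b = "".join(b)
            d = divergence_pct(a, b)
            d_rc = divergence_pct(a.translate(comp)[::-1], b.translate(comp)[::-1])
            assert d == pytest.approx(d_rc)


class TestDotPlot:
    def test_self_plot_contains_diagonal(self, rng):
        s = "".join(rng.choice(list("ACGT"), 60))
        plot = dotplot(s, s, word_size=8)
        for i in range(1, 60 - 8 + 2):
            assert (i, i) in plot.hits

    def test_no_hits_between_unrelated_words(self):
        assert dotplot("ACGTACGT", "TTTTTTTT", 4, 1).hits == set()

    def test_n_never_matches(self):
        assert dotplot("ANGT" * 3, "ANGT" * 3, 4, 1).hits == set()

    def test_short_sequence_warns(self):
        plot = dotplot("ACG", "ACGTACGT", 4, 1)
        assert plot.hits == set()
        assert plot.warning is not None

    def test_provirus_against_own_ltr_shows_two_diagonals(self, rng):
        ltr = "".join(rng.choice(list("ACGT"), 80))
        internal = "".join(rng.choice(list("ACGT"), 300))
        provirus = ltr + internal + ltr
        plot = dotplot(provirus, ltr, word_size=11)
        starts = {i for i, _ in plot.hits}
        offset3 = len(ltr) + len(internal)
        assert 1 in starts and (offset3 + 1) in starts
        # hits form two diagonal segments at offsets 0 and offset3
        for i, j in plot.hits:
            assert i - j in (0, offset3)


class TestCoverageFraction:
    def test_full_and_absent(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 200))
        plot = dotplot(ref, ref, word_size=11)
        assert coverage_fraction(plot, (50, 150), axis="b") == 1.0
        unrelated = "".join(rng.choice(list("ACGT"), 200))
        plot2 = dotplot(unrelated, ref, word_size=11)
        assert coverage_fraction(plot2, (50, 150), axis="b") == pytest.approx(
            0.0, abs=0.02
        )

    def test_half_deleted_feature_matches_word_enumeration(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 400))
        feature = (101, 300)
        # delete the central half of the feature from the query
        query = ref[:150] + ref[250:]
        w = 11
        plot = dotplot(query, ref, word_size=w)
        measured = coverage_fraction(plot, feature, axis="b")
        # independent enumeration: reference word starts whose word occurs
        # anywhere in the query
        qwords = {query[i : i + w] for i in range(len(query) - w + 1)}
        starts = [p for p in range(feature[0], feature[1] - w + 2)]
        expected = sum(ref[p - 1 : p - 1 + w] in qwords for p in starts) / len(starts)
        assert measured == pytest.approx(expected)
        assert 0.35 < measured < 0.60

    def test_interval_outside_dims_rejected(self):
        plot = dotplot("ACGTACGTACGT", "ACGTACGTACGT", 4, 1)
        with pytest.raises(ValueError):
            coverage_fraction(plot, (5, 999), axis="b")

    def test_enlarging_deletion_never_increases_coverage(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 600))
        feature = (101, 500)
        prev = 1.0
        for frac in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            del_len = int(400 * frac)
            query = ref[:200] + ref[200 + del_len :]
            cov = coverage_fraction(
                dotplot(query, ref, word_size=11), feature, axis="b"
            )
            assert cov <= prev + 1e-9
            prev = cov


class TestScoringScheme:
    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=-1, mismatch=1)
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=2)
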