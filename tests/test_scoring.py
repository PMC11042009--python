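"""Determinant scoring: b(t), document distribution, and the a(t) mean.

The reference oracle here recounts everything with nested loops directly
over raw token lists, independent of the Counter-based implementation.
"""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from detscore.scoring import (
    TermStatistics,
    build_test_set,
    distribution_fraction,
    proportional_occurrence,
    score_all,
    score_term,
    term_counts,
)

from conftest import ndoc


def brute_force_stats(pos_token_lists, neg_token_lists):
    """Nested-loop recount of every statistic, straight from token lists."""
    out = {}
    test_set = sorted({t for toks in pos_token_lists for t in toks})
    for term in test_set:
        n_pos = sum(1 for toks in pos_token_lists for t in toks if t == term)
        n_neg = sum(1 for toks in neg_token_lists for t in toks if t == term)
        containing = sum(1 for toks in pos_token_lists if term in toks)
        b = n_pos / (n_pos + n_neg)
        dist = containing / len(pos_token_lists)
        out[term] = {
            "n_pos": n_pos,
            "n_total": n_pos + n_neg,
            "doc_count_pos": containing,
            "b": b,
            "dist_fraction": dist,
            "score": (b + dist) / 2,
        }
    return out


class TestBuildTestSet:
    def test_exact_set_union(self):
        docs = [ndoc("1", "a b"), ndoc("2", "b c")]
        assert build_test_set(docs) == {"a", "b", "c"}

    def test_empty_document_contributes_nothing(self):
        docs = [ndoc("1", []), ndoc("2", "x")]
        assert build_test_set(docs) == {"x"}

    def test_no_frequency_threshold(self):
        docs = [ndoc("1", "common common common rare")]
        assert "rare" in build_test_set(docs)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_test_set([])


class TestComponentStatistics:
    @pytest.mark.parametrize(
        "n_pos, n_neg, expected",
        [(3, 1, 0.75), (5, 0, 1.0), (1, 1, 0.5)],
    )
    def test_proportional_occurrence(self, n_pos, n_neg, expected):
        pos = {"t": n_pos} if n_pos else {}
        neg = {"t": n_neg} if n_neg else {}
        assert proportional_occurrence("t", pos, neg) == expected

    def test_absent_term_is_an_error_not_zero(self):
        with pytest.raises(ValueError):
            proportional_occurrence("ghost", {"x": 1}, {"y": 1})

    def test_distribution_counts_documents_not_occurrences(self):
        docs = [ndoc("1", ["t"] * 50), ndoc("2", "other")]
        assert distribution_fraction("t", docs) == 0.5

    @pytest.mark.parametrize("present, total, expected", [(9, 9, 1.0), (1, 9, 1 / 9)])
    def test_distribution_fraction(self, present, total, expected):
        docs = [ndoc(str(i), "t filler" if i < present else "filler") for i in range(total)]
        assert distribution_fraction("t", docs) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "b, dist, expected",
        [(1.0, 1.0, 1.0), (0.8, 1.0, 0.9), (0.5, 0.0, 0.25)],
    )
    def test_score_is_arithmetic_mean(self, b, dist, expected):
        assert score_term(b, dist) == pytest.approx(expected)

    @pytest.mark.parametrize("b, dist", [(-0.1, 0.5), (0.5, 1.2), (2.0, 2.0)])
    def test_out_of_range_inputs_rejected(self, b, dist):
        with pytest.raises(ValueError):
            score_term(b, dist)


class TestScoreAll:
    def test_hand_counted_example(self):
        pos = [ndoc("p", "x x y")]
        neg = [ndoc("n", "y")]
        by_term = {s.term: s for s in score_all(pos, neg)}
        assert set(by_term) == {"x", "y"}
        assert by_term["x"].b == 1.0
        assert by_term["x"].dist_fraction == 1.0
        assert by_term["x"].score == 1.0
        assert by_term["y"].b == 0.5
        assert by_term["y"].dist_fraction == 1.0
        assert by_term["y"].score == 0.75

    def test_disjoint_vocabularies_give_b_one(self):
        pos = [ndoc("p1", "a b"), ndoc("p2", "a")]
        neg = [ndoc("n1", "z z")]
        for s in score_all(pos, neg):
            assert s.b == 1.0
            assert s.score == (1.0 + s.dist_fraction) / 2

    def test_negative_only_terms_not_scored(self):
        pos = [ndoc("p", "a")]
        neg = [ndoc("n", "a ghost")]
        assert {s.term for s in score_all(pos, neg)} == {"a"}

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            score_all([], [ndoc("n", "x")])
        with pytest.raises(ValueError):
            score_all([ndoc("p", "x")], [])

    def test_matches_brute_force_on_random_tiny_corpora(self):
        rng = random.Random(20240901)
        vocab = list("abcdefgh")
        for _ in range(200):
            pos_lists = [
                [rng.choice(vocab) for _ in range(rng.randint(1, 20))]
                for _ in range(rng.randint(1, 5))
            ]
            neg_lists = [
                [rng.choice(vocab) for _ in range(rng.randint(0, 20))]
                for _ in range(rng.randint(1, 5))
            ]
            pos = [ndoc(f"p{i}", t) for i, t in enumerate(pos_lists)]
            neg = [ndoc(f"n{i}", t) for i, t in enumerate(neg_lists)]
            expected = brute_force_stats(pos_lists, neg_lists)
            got = {s.term: s for s in score_all(pos, neg)}
            assert set(got) == set(expected)
            for term, exp in expected.items():
                s = got[term]
                assert s.n_pos == exp["n_pos"]
                assert s.n_total == exp["n_total"]
                assert s.doc_count_pos == exp["doc_count_pos"]
                assert s.b == exp["b"]
                assert s.dist_fraction == exp["dist_fraction"]
                assert s.score == exp["score"]

    def test_permutation_invariance(self):
        pos = [ndoc("p1", "a a b"), ndoc("p2", "b c"), ndoc("p3", "c c c")]
        neg = [ndoc("n1", "a x"), ndoc("n2", "c")]
        rng = random.Random(7)
        baseline = {s.term: (s.n_pos, s.n_total, s.doc_count_pos, s.score)
                    for s in score_all(pos, neg)}
        for _ in range(5):
            p, n = pos[:], neg[:]
            rng.shuffle(p)
            rng.shuffle(n)
            shuffled = {s.term: (s.n_pos, s.n_total, s.doc_count_pos, s.score)
                        for s in score_all(p, n)}
            assert shuffled == baseline

    def test_duplicating_positive_corpus_preserves_ratios(self):
        pos = [ndoc("p1", "a a b"), ndoc("p2", "b c")]
        neg = [ndoc("n1", "a c c")]
        base = {s.term: (s.b, s.dist_fraction) for s in score_all(pos, neg)}
        doubled_pos = pos + [ndoc(d.doc_id + "-copy", list(d.tokens)) for d in pos]
        doubled = {s.term: (s.b, s.dist_fraction) for s in score_all(doubled_pos, neg)}
        # dist is unchanged by duplication; b shifts because positive counts
        # double while negative counts do not, so compare dist only
        for term in base:
            assert doubled[term][1] == base[term][1]

    def test_score_one_iff_exclusive_and_ubiquitous(self):
        pos = [ndoc("p1", "star other"), ndoc("p2", "star")]
        neg = [ndoc("n1", "other")]
        by_term = {s.term: s for s in score_all(pos, neg)}
        assert by_term["star"].score == 1.0
        assert by_term["other"].score < 1.0


class TestTermStatisticsInvariants:
    def test_derived_ratios_are_exact(self):
        s = TermStatistics(term="t", n_pos=3, n_total=4, doc_count_pos=2, n_docs_pos=9)
        assert s.b == 3 / 4
        assert s.dist_fraction == 2 / 9
        assert s.score == (3 / 4 + 2 / 9) / 2

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_pos=5, n_total=4, doc_count_pos=1, n_docs_pos=2),   # n_pos > n_total
            dict(n_pos=1, n_total=1, doc_count_pos=3, n_docs_pos=2),   # docs exceed corpus
            dict(n_pos=0, n_total=0, doc_count_pos=0, n_docs_pos=2),   # undefined ratio
        ],
    )
    def test_inconsistent_counts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TermStatistics(term="t", **kwargs)


class TestScoreProperties:
    @given(
        b=st.floats(0, 1, allow_nan=False),
        dist=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=300, deadline=None)
    def test_bounds(self, b, dist):
        assert 0.0 <= score_term(b, dist) <= 1.0

    @given(
        b=st.floats(0, 1, exclude_max=True, allow_nan=False),
        dist=st.floats(0, 1, allow_nan=False),
        eps=st.floats(1e-6, 1.0, allow_nan=False),
    )
    @settings(max_examples=300, deadline=None)
    def test_strictly_increasing_in_b(self, b, dist, eps):
        hi = min(1.0, b + eps)
        # increments below float resolution of the sum cannot be ordered
        if hi - b >= 1e-9:
            assert score_term(hi, dist) > score_term(b, dist)

    @given(
        b=st.floats(0, 1, allow_nan=False),
        dist=st.floats(0, 1, exclude_max=True, allow_nan=False),
        eps=st.floats(1e-6, 1.0, allow_nan=False),
    )
    @settings(max_examples=300, deadline=None)
    def test_strictly_increasing_in_distribution(self, b, dist, eps):
        hi = min(1.0, dist + eps)
        if hi - dist >= 1e-9:
            assert score_term(b, hi) > score_term(b, dist)
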