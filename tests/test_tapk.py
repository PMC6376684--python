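"""Average precision, threshold selection, TAP scoring and tool comparison."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mdbench.tapk import (
    JudgedRecord,
    RankedRetrieval,
    TapThreshold,
    average_precision,
    build_retrievals,
    compare,
    evaluate,
    precision_at,
    select_threshold,
    tap,
)


def retrieval(flags, scores=None, t_q=None, query_id="q"):
    scores = scores or [float(i) for i in range(1, len(flags) + 1)]
    if t_q is None:
        t_q = max(1, sum(flags))
    return RankedRetrieval(
        query_id, [JudgedRecord(s, bool(f)) for s, f in zip(scores, flags)], t_q
    )


def tap_oracle(flags, scores, t_q, e0):
    """Direct evaluation of the thresholded-average-precision formula."""
    below = [i for i, s in enumerate(scores) if s <= e0]
    if below:
        j = below[-1] + 1
        p_cutoff = sum(flags[:j]) / j
    else:
        p_cutoff = 0.0
    total = p_cutoff
    for m in range(1, len(flags) + 1):
        if flags[m - 1] and scores[m - 1] <= e0:
            total += sum(flags[:m]) / m
    return total / (t_q + 1)


class TestPrecision:
    @pytest.mark.parametrize(
        ("flags", "m", "expected"),
        [([1], 1, 1.0), ([0, 1], 2, 0.5), ([0], 1, 0.0), ([1, 0, 1], 3, 2 / 3)],
    )
    def test_examples(self, flags, m, expected):
        assert precision_at(retrieval(flags), m) == pytest.approx(expected)

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            precision_at(retrieval([1]), 2)


class TestAveragePrecision:
    def test_perfect_retrieval(self):
        assert average_precision(retrieval([1, 1], t_q=2), math.inf) == 1.0

    def test_single_relevant_at_second_rank(self):
        assert average_precision(retrieval([0, 1], t_q=1), math.inf) == 0.5

    def test_zero_when_nothing_below_cutoff(self):
        assert average_precision(retrieval([1, 1], t_q=2), e0=0.0) == 0.0

    def test_all_ranks_reading_differs(self):
        r = retrieval([1, 0, 1], t_q=2)
        standard = average_precision(r, math.inf)
        literal = average_precision(r, math.inf, all_ranks=True)
        assert standard == pytest.approx((1 + 2 / 3) / 2)
        assert literal == pytest.approx((1 + 1 / 2 + 2 / 3) / 2)


class TestSelectThreshold:
    def test_bruteforce_example(self):
        r = retrieval([1, 0, 0], scores=[1e-10, 1e-5, 1e-3], t_q=1)
        assert select_threshold([r], k=1).e0 == 1e-5

    def test_all_relevant_gives_largest_score(self):
        r = retrieval([1, 1, 1], scores=[1.0, 2.0, 5.0], t_q=3)
        for k in (1, 3, 20):
            assert select_threshold([r], k).e0 == 5.0

    def test_monotone_in_k(self, rng=np.random.default_rng(42)):
        retrievals = []
        for i in range(10):
            n = int(rng.integers(1, 8))
            flags = rng.integers(0, 2, n).tolist()
            scores = sorted(rng.uniform(0, 1, n).tolist())
            retrievals.append(retrieval(flags, scores, t_q=max(1, sum(flags)), query_id=f"q{i}"))
        previous = -math.inf
        for k in (1, 2, 3, 5, 20):
            e0 = select_threshold(retrievals, k).e0
            assert e0 >= previous
            previous = e0

    def test_maximality_against_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            retrievals = []
            for i in range(5):
                n = int(rng.integers(1, 7))
                flags = rng.integers(0, 2, n).tolist()
                scores = sorted(np.round(rng.uniform(0, 1, n), 2).tolist())
                retrievals.append(retrieval(flags, scores, query_id=f"q{i}"))
            k = int(rng.integers(1, 4))
            e0 = select_threshold(retrievals, k).e0

            def median_irrelevant(cutoff):
                counts = sorted(
                    sum(1 for rec in r.records if not rec.relevant and rec.score <= cutoff)
                    for r in retrievals
                )
                return counts[(len(counts) - 1) // 2]

            candidates = sorted({rec.score for r in retrievals for rec in r.records})
            admissible = [c for c in candidates if median_irrelevant(c) <= k]
            if admissible:
                assert e0 == admissible[-1]
            else:
                assert e0 < candidates[0]

    def test_empty_cutoff_when_condition_unsatisfiable(self):
        # two irrelevant records tie at the smallest score, so even the
        # smallest candidate admits 2 > k=1 irrelevant records per query
        r = retrieval([0, 0, 1], scores=[0.5, 0.5, 0.6], t_q=1)
        e0 = select_threshold([r], k=1).e0
        assert e0 < 0.5
        assert tap(r, e0) == 0.0

    def test_empty_retrieval_set_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            select_threshold([], 1)


class TestTap:
    def test_perfect_retrieval_is_one(self):
        r = retrieval([1, 1, 1], t_q=3)
        threshold = select_threshold([r], 1)
        assert tap(r, threshold) == 1.0

    def test_no_relevant_below_cutoff_is_zero(self):
        r = retrieval([0, 1], scores=[1.0, 2.0], t_q=1)
        assert tap(r, TapThreshold(1, 1.0)) == 0.0
        assert tap(r, TapThreshold(1, 0.5)) == 0.0

    def test_relevant_then_irrelevant(self):
        assert tap(retrieval([1, 0], t_q=1), TapThreshold(1, 2.0)) == pytest.approx(0.75)

    def test_irrelevant_then_relevant(self):
        assert tap(retrieval([0, 1], t_q=1), TapThreshold(1, 2.0)) == pytest.approx(0.5)

    def test_accepts_bare_float_threshold(self):
        assert tap(retrieval([1], t_q=1), 1.0) == 1.0

    @given(
        st.lists(st.booleans(), min_size=0, max_size=6),
        st.integers(0, 6),
        st.integers(0, 2),
    )
    def test_matches_oracle_and_stays_in_unit_interval(self, flags, cut_idx, extra_tq):
        flags = [int(f) for f in flags]
        scores = [float(i) for i in range(1, len(flags) + 1)]
        t_q = max(1, sum(flags)) + extra_tq
        e0 = 0.5 if cut_idx == 0 else float(min(cut_idx, len(flags)) or 0.5)
        r = retrieval(flags, scores, t_q=t_q)
        value = tap(r, e0)
        assert value == pytest.approx(tap_oracle(flags, scores, t_q, e0))
        assert 0.0 <= value <= 1.0

    @given(st.lists(st.booleans(), min_size=1, max_size=6), st.integers(1, 6))
    def test_algebraic_identity_with_average_precision(self, flags, cut_idx):
        flags = [int(f) for f in flags]
        scores = [float(i) for i in range(1, len(flags) + 1)]
        t_q = max(1, sum(flags))
        e0 = float(min(cut_idx, len(flags)))
        r = retrieval(flags, scores, t_q=t_q)
        cutoff = r.cutoff_rank(e0)
        p_e0 = precision_at(r, cutoff) if cutoff else 0.0
        expected = (average_precision(r, e0) * t_q + p_e0) / (t_q + 1)
        assert tap(r, e0) == pytest.approx(expected)

    def test_appending_irrelevant_above_cutoff_changes_nothing(self):
        base = retrieval([1, 0, 1], t_q=2)
        extended = retrieval([1, 0, 1, 0, 0], t_q=2)
        e0 = 3.0  # cutoff at the last original record
        assert tap(base, e0) == tap(extended, e0)
        assert average_precision(base, e0) == average_precision(extended, e0)


class TestEvaluate:
    def test_single_perfect_query(self):
        r = retrieval([1, 1], t_q=2)
        results = evaluate([r])
        assert sorted(results) == [1, 3, 5, 20]
        for result in results.values():
            assert result.mean == 1.0

    def test_single_empty_retrieval(self):
        r = RankedRetrieval("q", [], t_q=2)
        for result in evaluate([r]).values():
            assert result.scores["q"] == 0.0

    def test_t_q_zero_excluded_with_warning(self):
        good = retrieval([1], t_q=1, query_id="good")
        bad = RankedRetrieval("bad", [], t_q=0)
        with pytest.warns(UserWarning, match="T_q=0"):
            results = evaluate([good, bad], k_values=(1,))
        assert list(results[1].scores) == ["good"]

    def test_synthetic_set_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        retrievals = []
        for i in range(10):
            n = int(rng.integers(1, 9))
            flags = rng.integers(0, 2, n).tolist()
            scores = sorted(rng.uniform(0, 10, n).tolist())
            retrievals.append(
                retrieval(flags, scores, t_q=sum(flags) + int(rng.integers(0, 3)) or 1,
                          query_id=f"q{i}")
            )
        retrievals = [r for r in retrievals if r.t_q >= 1]
        results = evaluate(retrievals, k_values=(1, 3))
        for k, result in results.items():
            for r in retrievals:
                expected = tap_oracle(
                    [int(rec.relevant) for rec in r.records],
                    [rec.score for rec in r.records],
                    r.t_q,
                    result.e0,
                )
                assert result.scores[r.query_id] == pytest.approx(expected)


class TestCompare:
    def test_identical_lists(self):
        scores = [0.1, 0.5, 0.9, 0.3]
        result = compare(scores, scores)
        assert result.differences == [0.0] * 4
        assert result.pct_equal == 100.0
        assert result.mean_diff == 0.0
        assert result.p_value >= 0.5

    def test_uniform_shift_detected(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0.1, 0.7, 50)
        a = b + 0.2
        result = compare(a, b, "greater")
        assert result.mean_diff == pytest.approx(0.2)
        assert result.p_value < 0.05

    def test_asymptotic_p_close_to_exact_permutation_at_small_n(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.3, 1.0, 8)
        b = rng.uniform(0.0, 0.7, 8)
        ours = compare(a, b, "greater").p_value
        exact = stats.mannwhitneyu(a, b, alternative="greater", method="exact").pvalue
        assert ours == pytest.approx(exact, abs=0.02)

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare([], [1.0])

    def test_unequal_lengths_skip_paired_statistics(self):
        result = compare([0.1, 0.2, 0.3], [0.1, 0.2])
        assert result.differences is None and result.mean_diff is None
        assert math.isfinite(result.p_value)


class TestRankedRetrievalInvariants:
    def test_unsorted_records_rejected(self):
        with pytest.raises(ValueError, match="rank order"):
            RankedRetrieval("q", [JudgedRecord(2.0, True), JudgedRecord(1.0, False)], 1)

    def test_t_q_below_retrieved_relevant_rejected(self):
        with pytest.raises(ValueError, match="T_q"):
            retrieval([1, 1], t_q=1)


def test_build_retrievals_accepts_sets_and_counts():
    from mdbench.relevance import ARCHITECTURE_MATCH, RelevanceJudgment, SearchHit

    judged = {
        "q": [
            RelevanceJudgment(SearchHit("q", "t", 1e-4), True, ARCHITECTURE_MATCH, 1.0)
        ]
    }
    (from_set,) = build_retrievals(judged, {"q": {"t", "q"}})
    (from_count,) = build_retrievals(judged, {"q": 2})
    assert from_set.t_q == from_count.t_q == 2
    assert from_set.records == [JudgedRecord(1e-4, True)]
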