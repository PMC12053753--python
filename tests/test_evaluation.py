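"""Flat and DNF-aware scoring, F-beta arithmetic, aggregation behaviour."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_result
from trialdnf.evaluation import (
    MetricCounts,
    aggregate,
    evaluate_run,
    f_beta,
    round_half_up,
    score_dnf,
    score_flat,
    score_outcome,
)
from trialdnf.prompting import ExtractionOutcome


class TestScoreFlat:
    def test_identity(self):
        g = make_result([["A", "B"]])
        counts = score_flat(g, g)
        assert counts["inclusion"] == MetricCounts(2, 0, 0)

    def test_partial_overlap(self):
        g = make_result([["A", "B"]])
        p = make_result([["A", "C"]])
        assert score_flat(g, p)["inclusion"] == MetricCounts(1, 1, 1)

    def test_empty_empty(self):
        counts = score_flat(make_result([]), make_result([]))
        assert counts["inclusion"] == MetricCounts(0, 0, 0)

    def test_structure_is_ignored(self):
        g = make_result([["A", "B"]])
        p = make_result([["A"], ["B"]])
        assert score_flat(g, p)["inclusion"] == MetricCounts(2, 0, 0)


class TestScoreDnf:
    def test_clause_order_invariant(self, cohort_example):
        reordered = make_result([["HER2 +", "ER+"], ["FGFR amplification", "ER+"]])
        assert score_dnf(cohort_example, reordered)["inclusion"] == MetricCounts(2, 0, 0)

    def test_flat_perfect_dnf_wrong(self):
        g = make_result([["A", "B"]])
        p = make_result([["A"], ["B"]])
        assert score_dnf(g, p)["inclusion"] == MetricCounts(0, 2, 1)

    def test_single_clause_match(self):
        g = make_result([["A"]])
        assert score_dnf(g, g)["inclusion"].tp == 1

    def test_tp_bounded_by_clause_counts(self, small_corpus):
        import random

        rng = random.Random(0)
        golds = [a.gold for a in small_corpus]
        for g, p in zip(golds, rng.sample(golds, len(golds))):
            counts = score_dnf(g, p)["inclusion"]
            from trialdnf.dnf import canonicalize

            assert counts.tp <= min(
                len(canonicalize(g.inclusion)), len(canonicalize(p.inclusion))
            )

    def test_partial_credit_jaccard(self):
        g = make_result([["A", "B"]])
        p = make_result([["A", "B", "C"]])
        counts = score_dnf(g, p, partial_credit=True)["inclusion"]
        assert counts.tp == pytest.approx(2 / 3)
        assert counts.fp == 0 and counts.fn == 0


class TestFBeta:
    # (precision, recall, printed F2) cells whose published values the
    # formula 5PR/(4P+R) reproduces at 2 d.p.
    @pytest.mark.parametrize(
        "p, r, f2",
        [
            (1.0, 0.97, 0.98),
            (0.42, 0.77, 0.66),
            (0.55, 0.56, 0.56),
            (0.99, 0.93, 0.94),
            (0.65, 0.97, 0.88),
            (0.25, 0.95, 0.61),
            (0.99, 0.88, 0.90),
            (0.82, 0.96, 0.93),
            (0.63, 0.93, 0.85),
            (0.31, 0.95, 0.67),
            (0.86, 0.96, 0.94),
        ],
    )
    def test_published_cells(self, p, r, f2):
        assert round_half_up(f_beta(p, r, 2.0)) == f2

    @given(x=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_fixed_point(self, x):
        assert f_beta(x, x, 2.0) == pytest.approx(x)

    def test_zero_zero(self):
        assert f_beta(0.0, 0.0, 2.0) == 0.0

    def test_recall_weighted_above_f1(self):
        # beta=2 favours recall: whenever R > P, F2 > F1
        grid = [i / 10 for i in range(1, 11)]
        for p in grid:
            for r in grid:
                if r > p:
                    assert f_beta(p, r, 2.0) > f_beta(p, r, 1.0)

    @given(
        p1=st.floats(0.01, 1), p2=st.floats(0.01, 1), r=st.floats(0.01, 1)
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_precision(self, p1, p2, r):
        lo, hi = sorted((p1, p2))
        assert f_beta(lo, r, 2.0) <= f_beta(hi, r, 2.0) + 1e-12


class TestScoreOutcome:
    def _failure(self):
        return ExtractionOutcome("T", "zero_shot", "garbage", failure_reason="ParseFailure")

    def test_failure_scored_as_empty_prediction(self):
        gold = make_result([["A"], ["B"], ["C"]])
        counts = score_outcome(gold, self._failure(), "flat")
        assert counts["inclusion"] == MetricCounts(0, 0, 3)

    def test_failure_with_empty_gold(self):
        counts = score_outcome(make_result([]), self._failure(), "flat")
        assert counts["inclusion"] == MetricCounts(0, 0, 0)

    def test_success_delegates(self, cohort_example):
        outcome = ExtractionOutcome("T", "zero_shot", "raw", result=cohort_example)
        assert score_outcome(cohort_example, outcome, "dnf")["inclusion"].tp == 2


class TestAggregate:
    def test_micro_perfect(self):
        p, r, f2 = aggregate([MetricCounts(1, 0, 0), MetricCounts(1, 0, 0)], "micro")
        assert (p, r, f2) == (1.0, 1.0, 1.0)

    def test_micro_pools_counts(self):
        p, r, f2 = aggregate([MetricCounts(1, 1, 0), MetricCounts(0, 0, 1)], "micro")
        assert (p, r, f2) == (0.5, 0.5, 0.5)

    def test_macro_differs_from_micro(self):
        counts = [MetricCounts(1, 1, 0), MetricCounts(0, 0, 1)]
        # macro: per-trial (P,R,F2) = (0.5,1,0.833..) and (0,0,0), averaged
        p, r, f2 = aggregate(counts, "macro")
        assert p == pytest.approx(0.25)
        assert r == pytest.approx(0.5)
        assert (p, r) != aggregate(counts, "micro")[:2]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], "micro")

    def test_conservation(self, small_corpus):
        # Σtp + Σfn equals total gold units; Σtp + Σfp total predicted units
        import random

        from trialdnf.dnf import flatten_terms
        from trialdnf.synth import CorruptionConfig, corrupt_prediction

        rng = random.Random(4)
        cfg = CorruptionConfig(p_drop_term=0.3, p_add_term=0.2)
        total = MetricCounts()
        n_gold = n_pred = 0
        for a in small_corpus:
            o = corrupt_prediction(a.gold, cfg, rng, trial_id=a.trial_id)
            c = score_outcome(a.gold, o, "flat")["inclusion"]
            total = total + c
            n_gold += len(flatten_terms(a.gold.inclusion))
            n_pred += len(flatten_terms(o.result.inclusion))
        assert total.tp + total.fn == n_gold
        assert total.tp + total.fp == n_pred


class TestEvaluateRun:
    def test_oracle_grid_is_all_ones(self, small_corpus):
        outcomes = [
            ExtractionOutcome(a.trial_id, "zero_shot", "raw", result=a.gold)
            for a in small_corpus
        ]
        for report in evaluate_run(small_corpus, outcomes):
            assert report.precision == report.recall == report.f2 == 1.0
            assert report.n_parse_failures == 0

    def test_id_mismatch_lists_offenders(self, small_corpus):
        outcomes = [
            ExtractionOutcome("UNKNOWN", "zero_shot", "raw", result=small_corpus[0].gold)
        ]
        with pytest.raises(ValueError, match="UNKNOWN"):
            evaluate_run(small_corpus[:1], outcomes)

    def test_empty_outcomes_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            evaluate_run(small_corpus, [])
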