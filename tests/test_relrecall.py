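"""Confusion tables, the five retrieval metrics, and back-derivation."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from filterlab import relrecall, synthcorpus
from filterlab.corpus import ReferenceSet
from filterlab.ovidql import parse_strategy
from filterlab.relrecall import (
    ConfusionTable,
    back_derive_counts,
    build_confusion,
    compute_metrics,
    evaluate_review,
)

from conftest import make_record


class TestBuildConfusion:
    def test_set_arithmetic(self):
        ct = build_confusion(
            baseline_ids={str(i) for i in range(1, 11)},
            filter_ids={"1", "2", "3"},
            reference=ReferenceSet("r", frozenset({"1", "4"})),
        )
        assert (ct.a, ct.b, ct.c, ct.d) == (1, 2, 1, 6)

    def test_filter_equals_baseline(self):
        ct = build_confusion({"1", "2", "3"}, {"1", "2", "3"},
                             ReferenceSet("r", frozenset({"1"})))
        assert ct.d == 0
        assert ct.total == 3

    def test_empty_filter(self):
        ct = build_confusion({"1", "2"}, set(), ReferenceSet("r", frozenset({"1"})))
        assert (ct.a, ct.b) == (0, 0)

    def test_reference_outside_baseline_listed(self):
        with pytest.raises(ValueError, match="99"):
            build_confusion({"1"}, set(), ReferenceSet("r", frozenset({"1", "99"})))


class TestComputeMetrics:
    def test_published_takagi_cells(self):
        m = compute_metrics(ConfusionTable(a=7, b=80, c=0, d=13))
        assert m.sensitivity == 100.0
        assert m.specificity == pytest.approx(13.98, abs=0.005)
        assert m.precision == pytest.approx(8.05, abs=0.005)
        assert m.nnr == pytest.approx(12.43, abs=0.005)
        assert m.time_saved == pytest.approx(13.0)
        assert m.rounded() == {
            "sensitivity": 100, "specificity": 14, "precision": 8,
            "nnr": 12, "time_saved": 13,
        }

    def test_published_kamiya_cells(self):
        m = compute_metrics(ConfusionTable(a=12, b=58, c=0, d=50))
        assert m.precision == pytest.approx(17.14, abs=0.005)
        assert m.nnr == pytest.approx(5.83, abs=0.005)
        assert m.time_saved == pytest.approx(41.67, abs=0.005)
        assert m.rounded() == {
            "sensitivity": 100, "specificity": 46, "precision": 17,
            "nnr": 6, "time_saved": 42,
        }

    def test_perfect_filter(self):
        m = compute_metrics(ConfusionTable(a=1, b=0, c=0, d=1))
        assert (m.sensitivity, m.specificity, m.precision) == (100, 100, 100)
        assert (m.nnr, m.time_saved) == (1, 50)

    def test_empty_retrieval_flags_precision(self):
        m = compute_metrics(ConfusionTable(a=0, b=0, c=2, d=8))
        assert not m.precision_defined
        assert math.isnan(m.precision) and math.isnan(m.nnr)
        assert (m.sensitivity, m.time_saved) == (0.0, 100.0)

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionTable(a=0, b=5, c=0, d=5))


class TestBackDerive:
    @pytest.mark.parametrize(
        "args, cells",
        [
            ((3, 1314, 100, 37), (3, 826, 0, 485)),
            ((16, 784, 31.25, 70), (5, 230, 11, 538)),
            ((7, 100, 100, 14), (7, 80, 0, 13)),
        ],
    )
    def test_published_rows(self, args, cells):
        ct = back_derive_counts(*args)
        assert (ct.a, ct.b, ct.c, ct.d) == cells

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            back_derive_counts(10, 5, 100, 50)
        with pytest.raises(ValueError):
            back_derive_counts(5, 10, 120, 50)

    @given(
        st.integers(1, 50),
        st.integers(0, 2000),
        st.floats(0, 100),
        st.floats(0, 100),
    )
    def test_conservation(self, n, extra, sens, spec):
        total = n + extra + 1
        ct = back_derive_counts(n, total, sens, spec)
        assert ct.total == total
        assert ct.reference_size == n


def test_fixture_round_trip_all_twelve_rows():
    """Back-derived cells regenerate every printed metric, with the
    documented rounding exceptions pinned to their recomputed values."""
    rows = synthcorpus.published_evaluations()
    assert len(rows) == 12
    for row in rows.values():
        m = compute_metrics(row.counts)
        rounded = m.rounded(
            sens_decimals=row.sens_decimals,
            precision_decimals=row.precision_decimals,
        )
        for cell, printed in row.printed.items():
            if cell in row.recomputed_differs:
                # information lost to the published rounding chain:
                # our recomputation is pinned, the printed value retained
                assert rounded[cell] == pytest.approx(row.recomputed_differs[cell])
                assert rounded[cell] != pytest.approx(printed)
            else:
                assert rounded[cell] == pytest.approx(printed), (row.review, cell)


def test_fixture_included_counts_sum_to_73():
    rows = synthcorpus.published_evaluations()
    total = sum(r.included_n for r in rows.values() if r.filter_name == "pf_filter")
    assert total == 73


class TestEvaluateReview:
    def test_reference_records_all_match(self, pf_filter, toy_tree):
        records = [
            make_record(i, title=f"Prognosis of condition {i}") for i in range(5)
        ] + [make_record(9, title="unrelated filler")]
        ref = ReferenceSet("r", frozenset(str(i) for i in range(5)))
        ct, m = evaluate_review(records, pf_filter, toy_tree, ref)
        assert m.sensitivity == 100.0

    def test_strategy_matching_nothing(self, toy_tree):
        strat = parse_strategy("1 unmatchable.tw")
        records = [make_record(1, title="alpha"), make_record(2, title="beta")]
        ref = ReferenceSet("r", frozenset({"1"}))
        ct, m = evaluate_review(records, strat, toy_tree, ref)
        assert (m.sensitivity, m.time_saved) == (0.0, 100.0)

    def test_conservation_and_monotonicity_on_synthetic_corpus(self, toy_tree):
        spec = synthcorpus.CorpusSpec(n_relevant=40, n_irrelevant=160,
                                      mean_abstract_length=30, seed=3)
        records, ref = synthcorpus.generate(spec)
        narrow = parse_strategy("1 risk.tw")
        wide = parse_strategy("1 risk.tw\n2 survival.tw\n3 cohort.tw\n4 or/1-3")
        ct_n, m_n = evaluate_review(records, narrow, toy_tree, ref)
        ct_w, m_w = evaluate_review(records, wide, toy_tree, ref)
        assert ct_n.total == ct_w.total == len(records)
        assert m_w.sensitivity >= m_n.sensitivity
        assert m_w.specificity <= m_n.specificity
        assert m_w.time_saved <= m_n.time_saved

    def test_planted_probabilities_match_closed_form(self, toy_tree):
        """OR-filter sensitivity tracks 100*(1 - prod(1 - p_i)) on relevant
        records (binomial Monte-Carlo tolerance at n = 300)."""
        terms = (("alphaterm", 0.5, 0.05), ("betaterm", 0.4, 0.05))
        spec = synthcorpus.CorpusSpec(
            n_relevant=300, n_irrelevant=300, signal_terms=terms, mesh_signal=(),
            mean_abstract_length=20, seed=17,
        )
        records, ref = synthcorpus.generate(spec)
        strat = parse_strategy("1 alphaterm.tw\n2 betaterm.tw\n3 or/1-2")
        _, m = evaluate_review(records, strat, toy_tree, ref)
        expected = 100 * (1 - 0.5 * 0.6)  # 70%
        # 3 sigma of Binomial(300, 0.7) in percent: ~7.9
        assert abs(m.sensitivity - expected) < 8.0
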