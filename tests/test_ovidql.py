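"""Strategy parsing and Boolean query evaluation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from filterlab import ovidql
from filterlab.corpus import MeshTree
from filterlab.ovidql import (
    LineCombo,
    MeshExp,
    MeshNoExp,
    TextWord,
    apply_strategy,
    evaluate_line,
    parse_strategy,
)

from conftest import make_record


class TestParsing:
    def test_single_textword(self):
        strat = parse_strategy("1 risk.tw")
        assert strat.lines == [(1, TextWord("risk", truncated=False))]

    def test_quoted_truncated_textword(self):
        strat = parse_strategy('1 "prognos*".tw')
        assert strat.lines[0][1] == TextWord("prognos", truncated=True)

    def test_exploded_and_plain_headings(self):
        strat = parse_strategy("1 exp Cohort Studies/\n2 Prognosis/\n3 1 or 2")
        assert strat.lines[0][1] == MeshExp("Cohort Studies")
        assert strat.lines[1][1] == MeshNoExp("Prognosis")
        assert strat.lines[2][1] == LineCombo("or", (1, 2))

    def test_en_dash_range(self):
        strat = parse_strategy("1 a.tw\n2 b.tw\n3 or/1–2")
        assert strat.lines[2][1] == LineCombo("or", (1, 2))

    def test_forward_reference_rejected(self):
        with pytest.raises(ValueError, match="line 2"):
            parse_strategy("1 risk.tw\n2 or/1-5")

    def test_unknown_field_suffix_rejected(self):
        with pytest.raises(ValueError, match=r"\.mp"):
            parse_strategy("1 risk.mp")

    def test_embedded_wildcard_rejected(self):
        with pytest.raises(ValueError, match="wildcard"):
            parse_strategy('1 "pro*gnosis".tw')

    def test_pf_filter_structure(self, pf_filter):
        assert len(pf_filter) == 14
        final = pf_filter.lines[-1][1]
        assert final == LineCombo("or", tuple(range(1, 14)))
        textwords = [n for n in pf_filter.leaves() if isinstance(n, TextWord)]
        assert sorted({t.term for t in textwords}) == [
            "causal factor", "cohort", "course", "incidence",
            "predict", "prognos", "risk", "survival",
        ]
        assert sum(isinstance(n, MeshExp) for n in pf_filter.leaves()) == 5

    def test_haynes_structure(self, haynes_broad):
        assert len(haynes_broad.leaves()) == 6
        truncated = [
            n.term for n in haynes_broad.leaves()
            if isinstance(n, TextWord) and n.truncated
        ]
        assert sorted(truncated) == ["course", "predict", "prognos"]

    @pytest.mark.parametrize("name", ["pf_filter", "haynes_broad"])
    def test_builtin_round_trips(self, name):
        strat = ovidql.builtin_strategies()[name]
        assert parse_strategy(strat.to_text(), name=name).lines == strat.lines
        assert ovidql.strategy_from_dict(strat.to_dict()).lines == strat.lines


class TestEvaluateLine:
    def test_truncation_matches_token_prefix(self, toy_tree):
        rec = make_record(1, title="Prognostic significance of X")
        assert evaluate_line(TextWord("prognos", truncated=True), rec, toy_tree)
        assert not evaluate_line(TextWord("prognos", truncated=False), rec, toy_tree)

    def test_multiword_adjacency(self, toy_tree):
        hit = make_record(1, title="t", abstract="was a causal factor in disease")
        miss = make_record(2, title="t", abstract="a causal risk factor in disease")
        node = TextWord("causal factor")
        assert evaluate_line(node, hit, toy_tree)
        assert not evaluate_line(node, miss, toy_tree)

    def test_match_is_whole_token_and_case_insensitive(self, toy_tree):
        rec = make_record(1, title="Risky business")
        assert not evaluate_line(TextWord("risk"), rec, toy_tree)
        rec2 = make_record(2, title="RISK of events")
        assert evaluate_line(TextWord("risk"), rec2, toy_tree)

    def test_hyphenated_tokens_split(self, toy_tree):
        rec = make_record(1, title="Disease-free-survival endpoints")
        assert evaluate_line(TextWord("survival"), rec, toy_tree)

    def test_explosion_vs_noexp(self, toy_tree):
        rec = make_record(1, title="t", mesh=["Risk Factors"])
        assert evaluate_line(MeshExp("Risk"), rec, toy_tree)
        assert not evaluate_line(MeshNoExp("Risk"), rec, toy_tree)

    def test_empty_tree_degrades_to_exact_match(self):
        empty = MeshTree()
        rec = make_record(1, title="t", mesh=["Risk"])
        assert evaluate_line(MeshExp("Risk"), rec, empty)
        rec2 = make_record(2, title="t", mesh=["Risk Factors"])
        assert not evaluate_line(MeshExp("Risk"), rec2, empty)


def _toy_corpus():
    return [
        make_record(1, title="Survival after surgery"),
        make_record(2, title="Background study", mesh=["Incidence"]),
        make_record(3, title="t", abstract="outcomes were predicted by age"),
        make_record(4, title="Nothing relevant here", abstract="plain text"),
    ]


class TestApplyStrategy:
    def test_pf_filter_on_toy_corpus(self, pf_filter, toy_tree):
        retrieved = apply_strategy(pf_filter, _toy_corpus(), toy_tree)
        assert retrieved == {"1", "2", "3"}

    def test_empty_corpus(self, pf_filter, toy_tree):
        assert apply_strategy(pf_filter, [], toy_tree) == frozenset()

    def test_single_leaf_equals_leaf_match_set(self, toy_tree):
        strat = parse_strategy("1 survival.tw")
        corpus = _toy_corpus()
        expected = {
            r.id
            for r in corpus
            if evaluate_line(TextWord("survival"), r, toy_tree)
        }
        assert apply_strategy(strat, corpus, toy_tree) == expected

    def test_not_combo(self, toy_tree):
        strat = parse_strategy("1 survival.tw\n2 surgery.tw\n3 1 not 2")
        assert apply_strategy(strat, _toy_corpus(), toy_tree) == frozenset()

    def test_final_line_union_of_disjuncts(self, pf_filter, toy_tree):
        res = apply_strategy(pf_filter, _toy_corpus(), toy_tree, full_result=True)
        union = frozenset().union(*(res.line_sets[i] for i in range(1, 14)))
        assert res.retrieved == union


# --- property tests on random corpora -------------------------------------

_words = st.sampled_from(
    "risk cohort survival prognosis prognostic predicted course "
    "incidence causal factor alpha beta gamma delta".split()
)
_mesh = st.sampled_from(
    ["Risk", "Risk Factors", "Cohort Studies", "Prognosis", "Incidence",
     "Mortality", "Survival Analysis", "Disease-Free Survival", "Prevalence"]
)
_record = st.builds(
    lambda i, title, ab, mesh: make_record(
        i, title=" ".join(title) or "t", abstract=" ".join(ab), mesh=mesh
    ),
    st.uuids().map(str),
    st.lists(_words, max_size=8),
    st.lists(_words, max_size=20),
    st.sets(_mesh, max_size=4),
)
_corpora = st.lists(_record, max_size=40)


def _naive_eval(strategy, record, tree):
    """Per-record recursive oracle, independent of the set algebra."""
    values = {}
    for number, node in strategy.lines:
        if isinstance(node, LineCombo):
            bits = [values[r] for r in node.line_refs]
            if node.op == "or":
                values[number] = any(bits)
            elif node.op == "and":
                values[number] = all(bits)
            else:
                values[number] = bits[0] and not bits[1]
        else:
            values[number] = evaluate_line(node, record, tree)
    return values[strategy.final_line]


@given(_corpora)
def test_oracle_equivalence(records):
    """apply_strategy agrees with naive per-record re-evaluation."""
    from filterlab.synthcorpus import toy_mesh_tree

    tree = toy_mesh_tree()
    for strat in ovidql.builtin_strategies().values():
        expected = {r.id for r in records if _naive_eval(strat, r, tree)}
        assert apply_strategy(strat, records, tree) == expected


@given(_corpora)
def test_or_monotonicity(records):
    """Adding a disjunct to the final OR never shrinks the retrieved set."""
    from filterlab.synthcorpus import toy_mesh_tree

    tree = toy_mesh_tree()
    base = parse_strategy("1 risk.tw\n2 cohort.tw\n3 or/1-2")
    wider = parse_strategy("1 risk.tw\n2 cohort.tw\n3 survival.tw\n4 or/1-3")
    assert apply_strategy(base, records, tree) <= apply_strategy(wider, records, tree)


@given(_corpora, _mesh)
def test_exp_superset_of_noexp(records, heading):
    from filterlab.synthcorpus import toy_mesh_tree

    tree = toy_mesh_tree()
    exp = {r.id for r in records if evaluate_line(MeshExp(heading), r, tree)}
    noexp = {r.id for r in records if evaluate_line(MeshNoExp(heading), r, tree)}
    assert noexp <= exp
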