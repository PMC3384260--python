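"""Composition: argument rules, scalar operators, propagation, distribution."""

import pytest
from hypothesis import given, settings, strategies as st

from biocompose.compose import (
    ArgumentRule, CompositionConfig, apply_diminisher_intensifier,
    apply_modal, apply_negator, compose_document, compose_polarity,
    identify_arguments, propagate_arguments, rule_applies,
)
from biocompose.fixtures import (
    oracle_compose, random_graph, summarize_predications,
)
from biocompose.graph import EmbeddingGraph
from biocompose.lexicon import TriggerEntry
from biocompose.model import SurfaceElement, scope
from tests.conftest import compose_case, preds_by_lemma


# -----------------------------------------------------------------------------
# argument identification (rule-table semantics)


def _predicate_el(lemma, pos, sem="CAUSAL"):
    return SurfaceElement(
        id="v", tokens=(1,), char_span=(0, 4), sentence_index=0, text=lemma,
        lemma=lemma, pos=pos, binding="predicate",
        bound_object=TriggerEntry(lemma, pos, sem))


@pytest.mark.parametrize("rule,lemma,pos,sem,rel,applies", [
    # the five documented rule rows
    (ArgumentRule("PREP_ON", "NN", frozenset({"influence", "impact", "effect"}),
                  frozenset(), "Object"),
     "effect", "NN", "CAUSAL", "PREP_ON", True),
    (ArgumentRule("AGENT", "VB", frozenset(), frozenset(), "Subject"),
     "activate", "VBZ", "POSITIVE_REGULATION", "AGENT", True),
    (ArgumentRule("NSUBJPASS", "VB", frozenset(), frozenset(), "Object"),
     "bind", "VBD", "BINDING", "NSUBJPASS", True),
    (ArgumentRule("WHETHER_COMP", "VB", frozenset({"INTERROGATIVE"}),
                  frozenset(), "Object"),
     "examine", "VB", "INTERROGATIVE", "WHETHER_COMP", True),
    (ArgumentRule("PREP_IN", "NN", frozenset(),
                  frozenset({"effect", "role", "influence", "importance"}),
                  "Adjunct"),
     "upregulation", "NN", "POSITIVE_REGULATION", "PREP_IN", True),
    # exclusion fires: 'role' is excluded from PREP_IN adjuncts
    (ArgumentRule("PREP_IN", "NN", frozenset(),
                  frozenset({"effect", "role", "influence", "importance"}),
                  "Adjunct"),
     "role", "NN", "CAUSAL", "PREP_IN", False),
    # inclusion not met: 'binding' is not in the PREP_ON inclusion set
    (ArgumentRule("PREP_ON", "NN", frozenset({"influence", "impact", "effect"}),
                  frozenset(), "Object"),
     "binding", "NN", "BINDING", "PREP_ON", False),
    # semantic-type mismatch for the interrogative-only rule
    (ArgumentRule("WHETHER_COMP", "VB", frozenset({"INTERROGATIVE"}),
                  frozenset(), "Object"),
     "show", "VB", "DEMONSTRATIVE", "WHETHER_COMP", False),
])
def test_argument_rule_constraint_semantics(rule, lemma, pos, sem, rel, applies):
    assert rule_applies(rule, _predicate_el(lemma, pos, sem), rel) is applies


def test_rule_table_agrees_with_brute_force_over_all_rows(arg_rules):
    """First-match semantics: replaying the table by hand gives the same rule."""
    el = _predicate_el("effect", "NN", "CAUSAL")
    for rel in ("PREP_ON", "PREP_IN", "PREP_OF", "AGENT"):
        expected = next((r for r in arg_rules if rule_applies(r, el, rel)), None)
        got = [r for r in arg_rules if rule_applies(r, el, rel)]
        assert (got[0] if got else None) == expected


def test_identify_arguments_first_object_wins(arg_rules):
    g = EmbeddingGraph()
    v = _predicate_el("presume", "VBN", "ASSUMPTIVE")
    g.add_element(v)
    for i, rel in [(1, "XCOMP"), (2, "NSUBJPASS")]:
        g.add_element(SurfaceElement(
            id=f"c{i}", tokens=(i + 1,), char_span=(i * 10, i * 10 + 2),
            sentence_index=0, text=f"c{i}"))
        g.add_relation(rel, "v", f"c{i}")
    out = identify_arguments("v", g, arg_rules)
    objects = [(t, rel) for t, rel, _ in out if t == "Object"]
    assert objects == [("Object", "XCOMP")]   # second Object assignment skipped


# -----------------------------------------------------------------------------
# scalar operators


@pytest.mark.parametrize("trigger,embedded,expected", [
    ("neutral", "positive", "positive"),
    ("neutral", "negative", "negative"),
    ("negative", "positive", "negative"),
    ("negative", "negative", "negative"),
    ("positive", "negative", "negative"),
    ("positive", "positive", "positive"),
    ("positive", "neutral", "positive"),
    ("neutral", "neutral", "neutral"),
])
def test_polarity_composition_table(trigger, embedded, expected):
    assert compose_polarity(trigger, embedded) == expected


def test_negator_inverts_and_modal_rescales():
    assert apply_negator(1.0) == 0.0
    assert apply_negator(0.5) == 0.5
    assert apply_modal(0.7, 0.0) == pytest.approx(0.3)   # may not involve
    assert apply_modal(0.7, 1.0) == pytest.approx(0.7)   # presume/should
    assert apply_modal(1.0, 1.0) == 1.0
    assert apply_modal(1.0, 0.2) == pytest.approx(0.2)


def test_diminisher_and_intensifier_branches():
    dim = TriggerEntry("slightly", "RB", "DIMINISHER", "neutral", 0.7, False)
    assert apply_diminisher_intensifier(dim, 1.0) == pytest.approx(0.7)
    inten = TriggerEntry("strongly", "RB", "INTENSIFIER", "neutral", 0.8, False)
    assert apply_diminisher_intensifier(inten, 1.0) == 1.0   # already maximal
    assert apply_diminisher_intensifier(inten, 0.6) == pytest.approx(0.68)
    ident = TriggerEntry("x", "RB", "INTENSIFIER", "neutral", 1.0, False)
    assert apply_diminisher_intensifier(ident, 0.9) == pytest.approx(0.9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=1.0),
       st.lists(st.tuples(st.sampled_from(["neg", "modal", "dim", "int"]),
                          st.floats(min_value=0.0, max_value=1.0)),
                max_size=8))
def test_mv_stays_in_unit_interval_under_operator_sequences(mv, ops):
    for kind, s in ops:
        if kind == "neg":
            mv = apply_negator(mv)
        elif kind == "modal":
            mv = apply_modal(s, mv)
        else:
            sem = "DIMINISHER" if kind == "dim" else "INTENSIFIER"
            mv = apply_diminisher_intensifier(
                TriggerEntry("w", "RB", sem, "neutral", s, False), mv)
        assert 0.0 <= mv <= 1.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=1.0))
def test_negator_is_an_involution(mv):
    assert apply_negator(apply_negator(mv)) == pytest.approx(mv)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=1.0),
       st.floats(min_value=0.0, max_value=1.0))
def test_modal_branch_monotonicity(strength, mv):
    out = apply_modal(strength, mv)
    if mv >= 0.5:
        assert out <= mv + 1e-12      # lowers values close to 1
    else:
        assert out >= mv - 1e-12      # raises values in a negative context
    if strength == 1.0:
        assert out == pytest.approx(mv)


# -----------------------------------------------------------------------------
# worked-example composition


def test_modality_chain_may_not_involve(lexicon, arg_rules):
    _, _, preds = compose_case("ex12", lexicon, arg_rules)
    by = preds_by_lemma(preds)
    involve, = by["involve"]
    assert involve.mv == pytest.approx(0.3)
    assert involve.negated and involve.polarity == "negative"
    may, = by["may"]
    assert may.mv == pytest.approx(0.3)
    not_, = by["not"]
    assert not_.mv == pytest.approx(0.0)


def test_polarity_chain_lead_prevention_is_negative_causal(lexicon, arg_rules):
    _, _, preds = compose_case("ex11", lexicon, arg_rules)
    by = preds_by_lemma(preds)
    lead, = by["lead"]
    assert lead.semantic_type == "CAUSAL" and lead.polarity == "negative"
    assert by["prevention"][0].polarity == "negative"


def test_figure2_predication_types_and_scope_chain(lexicon, arg_rules):
    _, _, preds = compose_case("fig2", lexicon, arg_rules)
    by = preds_by_lemma(preds)
    types = {lemma: ps[0].semantic_type for lemma, ps in by.items()}
    assert types["presume"] == "ASSUMPTIVE"
    assert types["important"] == "SALIENCY"
    assert types["subsequent"] == "TEMPORAL"
    assert types["lead"] == "CAUSAL"
    assert types["phosphorylation"] == "PHOSPHORYLATION"
    in_scope = {p.predicate.lemma for p in scope(by["presume"][0])}
    assert {"important", "phosphorylation", "degradation"} <= in_scope
    assert {p.predicate.lemma for p in scope(by["important"][0])} == \
        {"phosphorylation", "degradation"}


def test_propagation_admits_il10_and_rejects_gp41(lexicon, arg_rules):
    _, _, preds = compose_case("ex13", lexicon, arg_rules)
    bind, = preds_by_lemma(preds)["bind"]
    arg_ids = {a.value.id for a in bind.args}
    assert "T2" in arg_ids        # IL-10, reached through two free nodes
    assert "T3" not in arg_ids    # gp41: PREP_AFTER licenses no rule
    assert bind.negated           # determiner negation ('no NF-kB bound')


def test_propagation_depth_limit_blocks_two_step_chains(lexicon, arg_rules):
    _, _, preds = compose_case("ex13", lexicon, arg_rules, depth=1)
    bind, = preds_by_lemma(preds)["bind"]
    assert "T2" not in {a.value.id for a in bind.args}


def test_propagate_arguments_orders_candidates_closest_first(lexicon):
    from tests.conftest import build_case_graph
    _, graph = build_case_graph("ex13", lexicon, coref=False)
    site = next(el for el in graph.elements() if el.text == "site")
    cands = propagate_arguments(site.id, graph)
    assert [graph.element(c).text for c in cands] == ["IL-10"]
    assert propagate_arguments(site.id, graph, depth=1) == []


def test_coordination_distribution_one_predication_per_conjunct(lexicon, arg_rules):
    _, _, preds = compose_case("ex27", lexicon, arg_rules)
    activated = preds_by_lemma(preds)["activate"]
    assert len(activated) == 3
    themes = {p.object.id for p in activated}
    assert themes == {"T1", "T2", "T3"}
    # the three predications differ only in the distributed slot
    assert len({p.semantic_type for p in activated}) == 1


def test_attributive_links_argument_into_embedded_predication(lexicon, arg_rules):
    _, _, preds = compose_case("ex8", lexicon, arg_rules)
    degradation, = preds_by_lemma(preds)["degradation"]
    assert degradation.object.id == "T1"      # p105, donated by 'undergoes'


def _raising_chain(raising: bool) -> EmbeddingGraph:
    """not >s think >s bind, with a configurable negative-raising flag."""
    g = EmbeddingGraph()
    specs = [("not", "RB", "NEGATOR", "negative", 1.0, False, (0, 3)),
             ("think", "VB", "EPISTEMIC", "positive", 0.9, raising, (4, 9)),
             ("bind", "VB", "BINDING", "neutral", 1.0, False, (10, 14))]
    for i, (lemma, pos, sem, pol, s, nr, span) in enumerate(specs, 1):
        g.add_element(SurfaceElement(
            id=lemma, tokens=(i,), char_span=span, sentence_index=0,
            text=lemma, lemma=lemma, pos=pos, binding="predicate",
            bound_object=TriggerEntry(lemma, pos, sem, pol, s, nr)))
    g.add_relation("NEG", "not", "think")
    g.add_relation("CCOMP", "think", "bind")
    return g


def test_negative_raising_transfers_negation_to_complement(arg_rules):
    # don't think P  =>  think over inverted P: the complement carries the
    # negation, modally rescaled (1 -> s -> 1-s)
    preds = {p.predicate.lemma: p
             for p in compose_document(_raising_chain(raising=True), arg_rules)}
    assert preds["bind"].negated
    assert preds["bind"].mv == pytest.approx(0.1)
    assert not preds["think"].negated


def test_without_raising_the_matrix_predicate_is_negated(arg_rules):
    preds = {p.predicate.lemma: p
             for p in compose_document(_raising_chain(raising=False), arg_rules)}
    assert preds["think"].negated
    assert not preds["bind"].negated
    assert preds["bind"].mv == pytest.approx(0.9)   # rescaled, not inverted


def test_empty_graph_composes_to_nothing(arg_rules):
    g = EmbeddingGraph()
    g.add_element(SurfaceElement(id="n1", tokens=(1,), char_span=(0, 3),
                                 sentence_index=0, text="the"))
    assert compose_document(g, arg_rules) == []


# -----------------------------------------------------------------------------
# composer vs brute-force oracle


@pytest.mark.parametrize("block", range(10))
def test_composer_matches_brute_force_oracle(block, arg_rules):
    """On random embedding trees the composer must equal the direct recursive
    evaluator of the argument/polarity/modality definitions."""
    for seed in range(block * 100, block * 100 + 100):
        graph = random_graph(seed, 3 + seed % 10)
        config = CompositionConfig(propagation_depth=None if seed % 3 else 1)
        got = summarize_predications(compose_document(graph, arg_rules, config))
        want = oracle_compose(graph, arg_rules, config)
        assert got == want, f"seed {seed}"


def test_random_graph_is_reproducible():
    a, b = random_graph(7, 9), random_graph(7, 9)
    assert [(e.id, e.binding) for e in a.elements()] == \
        [(e.id, e.binding) for e in b.elements()]
    assert a.arcs() == b.arcs()
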