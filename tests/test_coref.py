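"""Coreference: the four anaphora classes, constraints, blocking, selection."""

import pytest

from biocompose.coref import (
    DNP, PRON, AnaphorMention, CompatibilityLexicons, blocked,
    candidate_antecedents, compatible, resolve_appos, resolve_relat,
)
from biocompose.graph import EmbeddingGraph
from biocompose.lexicon import TriggerEntry
from biocompose.model import EntityMention, SurfaceElement
from tests.conftest import build_case_graph


def _coref_texts(graph):
    return {(graph.element(s).text, graph.element(t).text)
            for rel, s, t in graph.arcs() if rel == "COREF"}


# -----------------------------------------------------------------------------
# RELAT and APPOS


def test_relative_pronoun_resolves_to_modified_np_head(lexicon):
    # rel(presumed, which) + rcmod(phosphorylation, presumed)
    _, graph = build_case_graph("fig2", lexicon)
    assert ("which", "phosphorylation") in _coref_texts(graph)


def test_rel_without_rcmod_yields_no_arc(lexicon):
    g = EmbeddingGraph()
    for i, (text, lemma) in enumerate(
            [("presumed", "presume"), ("which", "which")], 1):
        g.add_element(SurfaceElement(
            id=f"n{i}", tokens=(i,), char_span=(i * 5, i * 5 + 4),
            sentence_index=0, text=text, lemma=lemma))
    g.add_relation("REL", "n1", "n2")
    assert resolve_relat(g) == []        # the rule needs both conjuncts


def test_no_relative_dependency_no_relat_arcs(lexicon):
    _, graph = build_case_graph("ex8", lexicon)
    assert resolve_relat(graph) == []


def test_abbreviation_apposition_normalises_anaphor_to_later_mention(lexicon):
    # interleukin-10 (IL-10): the abbreviation is the anaphor
    _, graph = build_case_graph("ex14", lexicon)
    assert ("IL-10", "interleukin-10") in _coref_texts(graph)


def test_appos_fires_regardless_of_argument_order():
    def make(flip):
        g = EmbeddingGraph()
        for i, text in enumerate(["gp41", "domain"], 1):
            g.add_element(SurfaceElement(
                id=f"n{i}", tokens=(i,), char_span=(i * 10, i * 10 + 4),
                sentence_index=0, text=text, lemma=text))
        g.add_relation("APPOS", *( ("n2", "n1") if flip else ("n1", "n2") ))
        return g
    for flip in (False, True):
        arcs = resolve_appos(make(flip))
        # anaphor is always the later mention
        assert arcs == [("n2", "n1")]


def test_graph_without_appositive_family_arcs_yields_none(lexicon):
    _, graph = build_case_graph("ex12", lexicon)
    assert resolve_appos(graph) == []


# -----------------------------------------------------------------------------
# compatibility constraints (DNP semantic constraints, PRON agreement)


def _node(text, lemma=None, pos="NN", binding="free", bound=None, conj=False):
    g = EmbeddingGraph()
    el = SurfaceElement(id="cand", tokens=(1,), char_span=(0, len(text)),
                        sentence_index=0, text=text, lemma=lemma or text.lower(),
                        pos=pos, binding=binding, bound_object=bound)
    g.add_element(el)
    if conj:
        for i in range(2):
            g.add_element(SurfaceElement(
                id=f"x{i}", tokens=(2 + i,), char_span=(10 + i, 11 + i),
                sentence_index=0, text=f"x{i}"))
            g.add_relation("CC", "cand", f"x{i}")
    return g, el


def _anaphor(head, klass=DNP, number="singular", node_bound=None):
    el = SurfaceElement(id="ana", tokens=(9,), char_span=(90, 99),
                        sentence_index=0, text=head, lemma=head, pos="NN",
                        binding="predicate" if node_bound else "free",
                        bound_object=node_bound)
    return AnaphorMention(node=el, klass=klass, number=number, head_lemma=head)


LEX = CompatibilityLexicons()


def test_dnp_head_word_constraint_cd4_gene():
    g, cand = _node("CD4 gene", lemma="cd4 gene", binding="entity",
                    bound=EntityMention("T1", "Protein", (0, 8), "CD4 gene"))
    assert compatible(_anaphor("gene"), cand, g, LEX)


def test_dnp_singular_hypernymy_accepts_protein_entity():
    g, cand = _node("TRADD", binding="entity",
                    bound=EntityMention("T1", "Protein", (0, 5), "TRADD"))
    assert compatible(_anaphor("protein"), cand, g, LEX)


def test_dnp_plural_hypernymy_accepts_conjunction():
    g, cand = _node("and", pos="CC", conj=True)
    assert compatible(_anaphor("factor", number="plural"), cand, g, LEX)
    # but a singular sortal anaphor does not take the (plural) conjunction
    assert not compatible(_anaphor("factor", number="singular"), cand, g, LEX)


def test_dnp_meronymy_accepts_conjunction():
    g, cand = _node("and", pos="CC", conj=True)
    assert compatible(_anaphor("dimer", number="plural"), cand, g, LEX)


def test_dnp_event_constraint_same_event_lexicalization():
    trig = TriggerEntry("phosphorylate", "VB", "PHOSPHORYLATION")
    g, cand = _node("phosphorylated", lemma="phosphorylate", pos="VBN",
                    binding="predicate", bound=trig)
    ana = _anaphor("phosphorylation",
                   node_bound=TriggerEntry("phosphorylation", "NN",
                                           "PHOSPHORYLATION"))
    assert compatible(ana, cand, g, LEX)
    other = _anaphor("expression",
                     node_bound=TriggerEntry("expression", "NN",
                                             "GENE_EXPRESSION"))
    assert not compatible(other, cand, g, LEX)


def test_pron_number_agreement_rejects_mismatch():
    g, cand = _node("and", pos="CC", conj=True)       # plural conjunction
    it = _anaphor("it", klass=PRON, number="singular")
    assert not compatible(it, cand, g, LEX)
    they = _anaphor("they", klass=PRON, number="plural")
    assert compatible(they, cand, g, LEX)


def test_pron_never_agrees_with_verbal_triggers():
    g, cand = _node("assumed", lemma="assume", pos="VBN", binding="predicate",
                    bound=TriggerEntry("assume", "VB", "ASSUMPTIVE"))
    assert not compatible(_anaphor("it", klass=PRON), cand, g, LEX)


# -----------------------------------------------------------------------------
# structural blocking


def _pair_graph(rel_a, rel_c):
    g = EmbeddingGraph()
    for nid, span in [("gov", (0, 3)), ("cand", (4, 8)), ("ana", (9, 12))]:
        g.add_element(SurfaceElement(id=nid, tokens=(1,), char_span=span,
                                     sentence_index=0, text=nid))
    if rel_c:
        g.add_relation(rel_c, "gov", "cand")
    if rel_a:
        g.add_relation(rel_a, "gov", "ana")
    return g


def test_blocked_by_direct_embedding():
    g = _pair_graph(None, None)
    g.add_relation("PREP_OF", "cand", "ana")
    ana = AnaphorMention(node=g.element("ana"), klass=PRON, number="singular")
    assert blocked(ana, g.element("cand"), g)


def test_blocked_subject_object_unless_reflexive():
    g = _pair_graph("DOBJ", "NSUBJ")
    ana = AnaphorMention(node=g.element("ana"), klass=PRON, number="singular")
    assert blocked(ana, g.element("cand"), g)
    itself = AnaphorMention(node=g.element("ana"), klass=PRON,
                            number="singular", reflexive=True)
    assert not blocked(itself, g.element("cand"), g)


def test_blocked_adjunct_anaphor_subject_antecedent():
    g = _pair_graph("PREP_IN", "NSUBJ")
    ana = AnaphorMention(node=g.element("ana"), klass=PRON, number="singular")
    assert blocked(ana, g.element("cand"), g)


def test_unrelated_distant_nodes_are_not_blocked(lexicon):
    _, graph = build_case_graph("ex16", lexicon)
    its = next(el for el in graph.elements() if el.text == "Its")
    eotaxin = next(el for el in graph.elements() if el.text == "Eotaxin")
    ana = AnaphorMention(node=its, klass=PRON, number="singular")
    assert not blocked(ana, eotaxin, graph)


# -----------------------------------------------------------------------------
# end-to-end resolution on the worked examples


@pytest.mark.parametrize("name,expected", [
    ("ex16", {("Its", "Eotaxin")}),
    ("ex23", {("their", "GATA3"), ("their", "FOXP3")}),
    ("ex24", {("factor", "APOBEC3G")}),
    ("ex27", {("they", "PKD1"), ("they", "PKD2"), ("they", "PKD3")}),
    ("ex26", {("their", "IL-2"), ("their", "IFN-gamma")}),
])
def test_pron_dnp_resolution_on_worked_examples(name, expected, lexicon):
    _, graph = build_case_graph(name, lexicon)
    assert expected <= _coref_texts(graph)


def test_coref_arcs_never_point_forward(lexicon, cases):
    for name in cases:
        _, graph = build_case_graph(name, lexicon)
        for rel, s, t in graph.arcs():
            if rel != "COREF":
                continue
            ana, ant = graph.element(s), graph.element(t)
            assert (ant.sentence_index, ant.char_span) \
                <= (ana.sentence_index, ana.char_span), name


def test_resolution_is_deterministic(lexicon):
    a = _coref_texts(build_case_graph("ex27", lexicon)[1])
    b = _coref_texts(build_case_graph("ex27", lexicon)[1])
    assert a == b


def test_candidates_exclude_semantically_free_nps(lexicon):
    # "PKD enzymes" is free and must not be offered as candidate for 'they'
    _, graph = build_case_graph("ex27", lexicon, coref=False)
    they = next(el for el in graph.elements() if el.text == "they")
    ana = AnaphorMention(node=they, klass=PRON, number="plural")
    cands = candidate_antecedents(ana, graph, LEX)
    assert "enzymes" not in {c.text for c in cands}


def test_first_sentence_anaphor_sees_only_prior_nodes(lexicon):
    _, graph = build_case_graph("ex12", lexicon, coref=False)
    upreg = next(el for el in graph.elements() if el.text == "upregulation")
    ana = AnaphorMention(node=upreg, klass=DNP, number="singular",
                         head_lemma="upregulation")
    for cand in candidate_antecedents(ana, graph, LEX):
        assert cand.char_span < upreg.char_span
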