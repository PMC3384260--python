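"""Built-in worked-example fixtures and randomized oracle graphs.

``builtin_cases`` encodes the worked examples the package is validated
against: document text, gold entities, dependency parses and the expected
predications or standoff output.  Dependency parses are authored by hand in
the collapsed-with-conjunct-propagation dialect (sentences are sometimes
shortened; the phenomena are preserved).

``random_graph`` generates small random embedding trees together with the
result of an independent brute-force evaluator (``oracle_compose``) that
applies the argument identification, propagation, polarity and modality
definitions directly — used to cross-check the production composer.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Optional

from .compose import (
    ArgumentRule, CompositionConfig, compose_polarity, rule_applies,
)
from .coref import DEFAULT_HYPERNYMS, CompatibilityLexicons
from .graph import EmbeddingGraph, ParsedSentence, SyntacticDependency, Token
from .lexicon import TriggerEntry
from .model import (
    ADJUNCT, NEGATIVE, OBJECT, SUBJECT,
    EntityMention, SurfaceElement, is_operator_type,
)
from .standoff import StandoffDocument


@dataclass
class FixtureCase:
    """A self-contained test input with its expected behaviour.

    ``expected`` is a free-form dict consumed by the test-suite assertions;
    ``provenance`` records whether the parse was printed in full in the
    source material or authored here.
    """

    name: str
    doc: StandoffDocument
    modules: frozenset[str] = frozenset()
    expected: dict = field(default_factory=dict)
    provenance: str = "authored"
    compat: Optional[CompatibilityLexicons] = None
    track: str = "GENIA"


def _sent(index: int, token_spec: str, dep_spec: str) -> ParsedSentence:
    """Build a sentence from compact specs.

    token_spec: whitespace-separated ``form|lemma|POS`` items (lemma may be
    omitted: ``form||POS`` or ``form|POS`` is not allowed — keep 3 fields).
    dep_spec: ``label(gov,dep)`` items separated by whitespace.
    """
    tokens = []
    for i, item in enumerate(token_spec.split(), 1):
        form, lemma, pos = item.split("|")
        tokens.append(Token(index=i, form=form, lemma=lemma or form.lower(), pos=pos))
    deps = []
    for item in dep_spec.split():
        label, rest = item.split("(", 1)
        gov, dep = rest.rstrip(")").split(",")
        deps.append(SyntacticDependency(label=label, governor=int(gov),
                                        dependent=int(dep)))
    return ParsedSentence(tokens=tokens, deps=deps, index=index)


def _doc(doc_id: str, text: str, entities: list[tuple[str, str, str]],
         sentences: list[ParsedSentence]) -> StandoffDocument:
    """Entities are (id, type, surface) triples located by first occurrence."""
    ents, cursor = [], {}
    for tid, etype, surface in entities:
        start = text.find(surface, cursor.get(surface, 0))
        if start < 0:
            raise ValueError(f"{doc_id}: entity text {surface!r} not in document")
        cursor[surface] = start + 1
        ents.append(EntityMention(id=tid, semantic_type=etype,
                                  char_span=(start, start + len(surface)),
                                  text=surface))
    return StandoffDocument(doc_id=doc_id, text=text, entities=ents,
                            sentences=sentences)


def builtin_cases() -> list[FixtureCase]:
    cases: list[FixtureCase] = []

    # -- figure-2 sentence: nested embedding, scope chain, unmapped types ----
    cases.append(FixtureCase(
        name="fig2",
        doc=_doc(
            "fig2",
            "Stimulation of cells leads to a rapid phosphorylation of "
            "IkappaBalpha, which is presumed to be important for the "
            "subsequent degradation.",
            [("T1", "Protein", "IkappaBalpha")],
            [_sent(0,
                   "Stimulation|stimulation|NN of|of|IN cells|cell|NNS "
                   "leads|lead|VBZ to|to|TO a|a|DT rapid|rapid|JJ "
                   "phosphorylation|phosphorylation|NN of|of|IN "
                   "IkappaBalpha|ikappabalpha|NN which|which|WDT is|be|VBZ "
                   "presumed|presume|VBN to|to|TO be|be|VB "
                   "important|important|JJ for|for|IN the|the|DT "
                   "subsequent|subsequent|JJ degradation|degradation|NN",
                   "prep_of(1,3) nsubj(4,1) prep_to(4,8) amod(8,7) "
                   "prep_of(8,10) rel(13,11) rcmod(8,13) xcomp(13,16) "
                   "nsubjpass(13,11) xsubj(16,11) prep_for(16,20) "
                   "det(20,18) amod(20,19)")],
        ),
        modules=frozenset({"graph", "coref", "compose", "mapping"}),
        expected={
            "types": {"stimulation": "POSITIVE_REGULATION", "lead": "CAUSAL",
                      "phosphorylation": "PHOSPHORYLATION",
                      "presume": "ASSUMPTIVE", "important": "SALIENCY",
                      "subsequent": "TEMPORAL",
                      "degradation": "PROTEIN_CATABOLISM"},
            # presumed > important > {phosphorylation, degradation}
            "scope_chain": ("presume", "important",
                            {"phosphorylation", "degradation"}),
            "unmapped_lemmas": {"subsequent", "degradation"},
            "mapped_lemmas": {"lead", "phosphorylation"},
            "relat_coref": ("which", "phosphorylation"),
        },
    ))

    # -- attributive: p105 undergoes degradation -----------------------------
    cases.append(FixtureCase(
        name="ex8",
        doc=_doc(
            "ex8", "p105 undergoes degradation.",
            [("T1", "Protein", "p105")],
            [_sent(0, "p105|p105|NN undergoes|undergo|VBZ "
                      "degradation|degradation|NN",
                   "nsubj(2,1) dobj(2,3)")],
        ),
        modules=frozenset({"compose", "mapping"}),
        expected={"a2_events": [("Protein_catabolism", "degradation",
                                 [("Theme", "T1")])]},
    ))

    # -- polarity chain: leads to the prevention -> negative CAUSAL ----------
    cases.append(FixtureCase(
        name="ex11",
        doc=_doc(
            "ex11", "Bcl-2 overexpression leads to the prevention of expression.",
            [("T1", "Protein", "Bcl-2")],
            [_sent(0, "Bcl-2|bcl-2|NN overexpression|overexpression|NN "
                      "leads|lead|VBZ to|to|TO the|the|DT "
                      "prevention|prevention|NN of|of|IN "
                      "expression|expression|NN",
                   "nn(2,1) nsubj(3,2) prep_to(3,6) det(6,5) prep_of(6,8)")],
        ),
        modules=frozenset({"compose"}),
        expected={"polarity": {"lead": NEGATIVE, "prevention": NEGATIVE}},
    ))

    # -- modality chain: may not involve (0 -> 0.3) --------------------------
    cases.append(FixtureCase(
        name="ex12",
        doc=_doc(
            "ex12",
            "Thus, IL-10 upregulation in monocytes may not involve "
            "NF-kB activation.",
            [("T1", "Protein", "IL-10"), ("T2", "Protein", "NF-kB")],
            [_sent(0, "Thus|thus|RB IL-10|il-10|NN "
                      "upregulation|upregulation|NN in|in|IN "
                      "monocytes|monocyte|NNS may|may|MD not|not|RB "
                      "involve|involve|VB NF-kB|nf-kb|NN "
                      "activation|activation|NN",
                   "advmod(8,1) nn(3,2) nsubj(8,3) prep_in(3,5) aux(8,6) "
                   "neg(8,7) dobj(8,10) nn(10,9)")],
        ),
        modules=frozenset({"graph", "compose"}),
        expected={
            "chain_arcs": [("ADVMOD", "Thus", "may"), ("AUX", "may", "not"),
                           ("NEG", "not", "involve")],
            "topmost": "Thus",
            "mv": {"involve": 0.3, "may": 0.3},
            "negated": {"involve"},
        },
    ))

    # -- argument propagation: bound ... site ... IL-10; gp41 excluded -------
    cases.append(FixtureCase(
        name="ex13",
        doc=_doc(
            "ex13",
            "no NF-kB bound to the site of the IL-10 promoter after "
            "addition of gp41.",
            [("T1", "Protein", "NF-kB"), ("T2", "Protein", "IL-10"),
             ("T3", "Protein", "gp41")],
            [_sent(0, "no|no|DT NF-kB|nf-kb|NN bound|bind|VBD to|to|TO "
                      "the|the|DT site|site|NN of|of|IN the|the|DT "
                      "IL-10|il-10|NN promoter|promoter|NN after|after|IN "
                      "addition|addition|NN of|of|IN gp41|gp41|NN",
                   "det(2,1) nsubj(3,2) prep_to(3,6) det(6,5) prep_of(6,10) "
                   "det(10,8) nn(10,9) prep_after(3,12) prep_of(12,14)")],
        ),
        modules=frozenset({"compose", "mapping"}),
        expected={
            "bind_args_include": {"T2"},    # IL-10 via propagation
            "bind_args_exclude": {"T3"},    # gp41: PREP_AFTER licenses no rule
            "negated": {"bind"},
        },
    ))

    # -- the evidential sentence and its printed standoff annotations --------
    cases.append(FixtureCase(
        name="ex14",
        doc=_doc(
            "ex14",
            "Our previous results show that recombinant gp41 stimulates "
            "interleukin-10 (IL-10) production in human monocytes.",
            [("T1", "Protein", "gp41"), ("T2", "Protein", "interleukin-10"),
             ("T3", "Protein", "IL-10")],
            [_sent(0, "Our|our|PRP$ previous|previous|JJ results|result|NNS "
                      "show|show|VBP that|that|IN recombinant|recombinant|JJ "
                      "gp41|gp41|NN stimulates|stimulate|VBZ "
                      "interleukin-10|interleukin-10|NN IL-10|il-10|NN "
                      "production|production|NN in|in|IN human|human|JJ "
                      "monocytes|monocyte|NNS",
                   "poss(3,1) amod(3,2) nsubj(4,3) ccomp(4,8) amod(7,6) "
                   "nsubj(8,7) dobj(8,11) nn(11,9) abbrev(9,10) "
                   "prep_in(11,14) amod(14,13)")],
        ),
        modules=frozenset({"graph", "coref", "compose", "mapping"}),
        expected={
            "appos_coref": ("IL-10", "interleukin-10"),
            "a2": ("T4\tPositive_regulation 48 58\tstimulates\n"
                   "T5\tGene_expression 82 92\tproduction\n"
                   "E1\tPositive_regulation:T4 Theme:E2 Cause:T1\n"
                   "E2\tGene_expression:T5 Theme:T2\n"),
        },
    ))

    # -- failed to stimulate: SUCCESS/negative -> Negation -------------------
    cases.append(FixtureCase(
        name="ex7",
        doc=_doc(
            "ex7", "gp41 failed to stimulate IL-10 production.",
            [("T1", "Protein", "gp41"), ("T2", "Protein", "IL-10")],
            [_sent(0, "gp41|gp41|NN failed|fail|VBD to|to|TO "
                      "stimulate|stimulate|VB IL-10|il-10|NN "
                      "production|production|NN",
                   "nsubj(2,1) xcomp(2,4) xsubj(4,1) dobj(4,6) nn(6,5)")],
        ),
        modules=frozenset({"compose", "mapping"}),
        expected={
            "polarity": {"fail": NEGATIVE},
            "modifications": [("NEGATION", "stimulate")],
        },
    ))

    # -- inter-sentential PRON: Its -> Eotaxin -------------------------------
    cases.append(FixtureCase(
        name="ex16",
        doc=_doc(
            "ex16",
            "Eotaxin is a beta-chemokine assumed to be involved in "
            "inflammatory diseases. Its expression is stimulus-specific.",
            [("T1", "Protein", "Eotaxin")],
            [_sent(0, "Eotaxin|eotaxin|NN is|be|VBZ a|a|DT "
                      "beta-chemokine|beta-chemokine|NN assumed|assume|VBN "
                      "to|to|TO be|be|VB involved|involve|VBN in|in|IN "
                      "inflammatory|inflammatory|JJ diseases|disease|NNS",
                   "nsubj(4,1) det(4,3) partmod(4,5) xcomp(5,8) prep_in(8,11)"),
             _sent(1, "Its|its|PRP$ expression|expression|NN is|be|VBZ "
                      "stimulus-specific|stimulus-specific|JJ",
                   "poss(2,1) nsubj(4,2)")],
        ),
        modules=frozenset({"coref", "compose", "mapping"}),
        expected={
            "pron_coref": [("Its", "Eotaxin")],
            "a2_events": [("Gene_expression", "expression", [("Theme", "T1")])],
        },
    ))

    # -- plural PRON over a conjunction: their -> {GATA3, FOXP3} -------------
    cases.append(FixtureCase(
        name="ex23",
        doc=_doc(
            "ex23",
            "Although GATA3 and FOXP3 showed similar kinetics, their "
            "expression polarizes.",
            [("T1", "Protein", "GATA3"), ("T2", "Protein", "FOXP3")],
            [_sent(0, "Although|although|IN GATA3|gata3|NN and|and|CC "
                      "FOXP3|foxp3|NN showed|show|VBD similar|similar|JJ "
                      "kinetics|kinetics|NNS their|their|PRP$ "
                      "expression|expression|NN polarizes|polarize|VBZ",
                   "mark(5,1) nsubj(5,2) cc(2,3) conj_and(2,4) nsubj(5,4) "
                   "dobj(5,7) amod(7,6) advcl(10,5) poss(9,8) nsubj(10,9)")],
        ),
        modules=frozenset({"coref", "compose", "mapping"}),
        expected={
            "pron_coref": [("their", "GATA3"), ("their", "FOXP3")],
            "a2_events": [("Gene_expression", "expression", [("Theme", "T1")]),
                          ("Gene_expression", "expression", [("Theme", "T2")])],
        },
    ))

    # -- inter-sentential DNP: this restriction factor -> APOBEC3G -----------
    cases.append(FixtureCase(
        name="ex24",
        doc=_doc(
            "ex24",
            "APOBEC3G is expressed in lymphocytes. We examined the "
            "transcriptional regulation of this restriction factor.",
            [("T1", "Protein", "APOBEC3G")],
            [_sent(0, "APOBEC3G|apobec3g|NN is|be|VBZ expressed|express|VBN "
                      "in|in|IN lymphocytes|lymphocyte|NNS",
                   "nsubjpass(3,1) prep_in(3,5)"),
             _sent(1, "We|we|PRP examined|examine|VBD the|the|DT "
                      "transcriptional|transcriptional|JJ "
                      "regulation|regulation|NN of|of|IN this|this|DT "
                      "restriction|restriction|NN factor|factor|NN",
                   "nsubj(2,1) dobj(2,5) det(5,3) prep_of(5,9) det(9,7) "
                   "nn(9,8)")],
        ),
        modules=frozenset({"coref", "compose", "mapping"}),
        expected={
            "dnp_coref": [("factor", "APOBEC3G")],
            "a2_events_include": [("Regulation", "transcriptional regulation",
                                   [("Theme", "T1")])],
        },
    ))

    # -- set-instance DNP with an extended hypernym list ---------------------
    cases.append(FixtureCase(
        name="ex25",
        doc=_doc(
            "ex25",
            "CD3, CD2 and CD28 are distinct receptors. Engagement of any "
            "of these receptors induces rapid phosphorylation of proteins.",
            [("T1", "Protein", "CD3"), ("T2", "Protein", "CD2"),
             ("T3", "Protein", "CD28")],
            [_sent(0, "CD3|cd3|NN CD2|cd2|NN and|and|CC CD28|cd28|NN "
                      "are|be|VBP distinct|distinct|JJ "
                      "receptors|receptor|NNS",
                   "conj_and(1,2) cc(1,3) conj_and(1,4) nsubj(7,1) amod(7,6)"),
             _sent(1, "Engagement|engagement|NN of|of|IN any|any|DT "
                      "of|of|IN these|these|DT receptors|receptor|NNS "
                      "induces|induce|VBZ rapid|rapid|JJ "
                      "phosphorylation|phosphorylation|NN of|of|IN "
                      "proteins|protein|NNS",
                   "prep_of(1,3) prep_of(3,6) det(6,5) nsubj(7,1) dobj(7,9) "
                   "amod(9,8) prep_of(9,11)")],
        ),
        modules=frozenset({"coref", "compose", "mapping"}),
        compat=CompatibilityLexicons(
            hypernyms=DEFAULT_HYPERNYMS | {"receptor"}),
        expected={
            # the quantifier 'any' is ignored: engagement distributes over
            # all three antecedents (reproduced as-is, not corrected)
            "dnp_coref": [("receptors", "CD3"), ("receptors", "CD2"),
                          ("receptors", "CD28")],
            "binding_themes": {"T1", "T2", "T3"},
        },
    ))

    # -- PRON via free-node propagation: their respective promoter -----------
    cases.append(FixtureCase(
        name="ex26",
        doc=_doc(
            "ex26",
            "Runx1 activates IL-2 and IFN-gamma expression by binding to "
            "their promoter.",
            [("T1", "Protein", "Runx1"), ("T2", "Protein", "IL-2"),
             ("T3", "Protein", "IFN-gamma")],
            [_sent(0, "Runx1|runx1|NN activates|activate|VBZ IL-2|il-2|NN "
                      "and|and|CC IFN-gamma|ifn-gamma|NN "
                      "expression|expression|NN by|by|IN binding|binding|NN "
                      "to|to|TO their|their|PRP$ promoter|promoter|NN",
                   "nsubj(2,1) dobj(2,6) nn(6,3) cc(3,4) conj_and(3,5) "
                   "prepc_by(2,8) xsubj(8,1) prep_to(8,11) poss(11,10)")],
        ),
        modules=frozenset({"coref", "compose", "mapping"}),
        expected={
            "pron_coref": [("their", "IL-2"), ("their", "IFN-gamma")],
            "binding_pairs": [{"T1", "T2"}, {"T1", "T3"}],
        },
    ))

    # -- free antecedent skipped: they -> {PKD1, PKD2, PKD3} -----------------
    cases.append(FixtureCase(
        name="ex27",
        doc=_doc(
            "ex27",
            "The PKD family has members: PKD1, PKD2 and PKD3. PKD enzymes "
            "are expressed in cells, where they are activated.",
            [("T1", "Protein", "PKD1"), ("T2", "Protein", "PKD2"),
             ("T3", "Protein", "PKD3")],
            [_sent(0, "The|the|DT PKD|pkd|NN family|family|NN has|have|VBZ "
                      "members|member|NNS PKD1|pkd1|NN PKD2|pkd2|NN "
                      "and|and|CC PKD3|pkd3|NN",
                   "det(3,1) nn(3,2) nsubj(4,3) dobj(4,5) dep(5,6) "
                   "conj_and(6,7) cc(6,8) conj_and(6,9)"),
             _sent(1, "PKD|pkd|NN enzymes|enzyme|NNS are|be|VBP "
                      "expressed|express|VBN in|in|IN cells|cell|NNS "
                      "where|where|WRB they|they|PRP are|be|VBP "
                      "activated|activate|VBN",
                   "nn(2,1) nsubjpass(4,2) prep_in(4,6) rcmod(6,10) "
                   "nsubjpass(10,8)")],
        ),
        modules=frozenset({"coref", "compose", "mapping"}),
        expected={
            # the true antecedent "PKD enzymes" is semantically free and is
            # skipped; three events result (reproduced as-is)
            "pron_coref": [("they", "PKD1"), ("they", "PKD2"),
                           ("they", "PKD3")],
            "a2_event_types": {("Positive_regulation", "T1"),
                               ("Positive_regulation", "T2"),
                               ("Positive_regulation", "T3")},
        },
    ))

    # -- sortal anaphora by head word: the gene ------------------------------
    cases.append(FixtureCase(
        name="dnp_gene",
        doc=_doc(
            "dnp_gene",
            "The CD4 gene is expressed. The gene is regulated.",
            [("T1", "Protein", "CD4")],
            [_sent(0, "The|the|DT CD4|cd4|NN gene|gene|NN is|be|VBZ "
                      "expressed|express|VBN",
                   "det(3,1) nn(3,2) nsubjpass(5,3)"),
             _sent(1, "The|the|DT gene|gene|NN is|be|VBZ "
                      "regulated|regulate|VBN",
                   "det(2,1) nsubjpass(4,2)")],
        ),
        modules=frozenset({"coref"}),
        expected={"dnp_coref": [("gene", "gene")]},
    ))

    # -- ID-track PROCESS: zero participants retained ------------------------
    cases.append(FixtureCase(
        name="process_id",
        doc=_doc(
            "process_id", "Colonization occurs.",
            [],
            [_sent(0, "Colonization|colonization|NN occurs|occur|VBZ",
                   "nsubj(2,1)")],
        ),
        modules=frozenset({"mapping"}),
        track="ID",
        expected={"a2_events": [("Process", "Colonization", [])]},
    ))

    # -- the four transformation-rule rows -----------------------------------
    cases.append(FixtureCase(
        name="t3_np_internal",
        doc=_doc(
            "t3r1", "CD40 ligand interactions play a key role.",
            [("T1", "Protein", "CD40 ligand")],
            [_sent(0, "CD40|cd40|NN ligand|ligand|NN "
                      "interactions|interaction|NNS play|play|VBP a|a|DT "
                      "key|key|JJ role|role|NN",
                   "nn(3,2) nn(3,1) dobj(4,7) nsubj(4,3) det(7,5) amod(7,6)")],
        ),
        modules=frozenset({"graph"}),
        provenance="printed dependencies",
        expected={"arcs": [("NN", "interactions", "CD40 ligand")],
                  "absent_arcs": [("NN", "interactions", "ligand"),
                                  ("NN", "interactions", "CD40")]},
    ))
    cases.append(FixtureCase(
        name="t3_coordination",
        doc=_doc(
            "t3r2", "specifically binds and phosphorylates IkBa.",
            [("T1", "Protein", "IkBa")],
            [_sent(0, "specifically|specifically|RB binds|bind|VBZ "
                      "and|and|CC phosphorylates|phosphorylate|VBZ "
                      "IkBa|ikba|NN",
                   "advmod(2,1) conj_and(2,4) cc(2,3) dobj(2,5) dobj(4,5)")],
        ),
        modules=frozenset({"graph"}),
        provenance="printed dependencies",
        expected={"arcs": [("CC", "and", "binds"),
                           ("CC", "and", "phosphorylates")]},
    ))
    cases.append(FixtureCase(
        name="t3_inversion",
        doc=_doc(
            "t3r3", "possible involvement of HCMV.",
            [("T1", "Virus", "HCMV")],
            [_sent(0, "possible|possible|JJ involvement|involvement|NN "
                      "of|of|IN HCMV|hcmv|NN",
                   "amod(2,1) prep_of(2,4)")],
        ),
        modules=frozenset({"graph"}),
        provenance="printed dependencies",
        expected={"arcs": [("AMOD", "possible", "involvement"),
                           ("PREP_OF", "involvement", "HCMV")],
                  "absent_arcs": [("AMOD", "involvement", "possible")]},
    ))
    cases.append(FixtureCase(
        name="t3_corrective",
        doc=_doc(
            "t3r4", "Tat and Sp1 proteins.",
            [("T1", "Protein", "Tat"), ("T2", "Protein", "Sp1")],
            [_sent(0, "Tat|tat|NN and|and|CC Sp1|sp1|NN "
                      "proteins|protein|NNS",
                   "nn(4,3) conj_and(1,4) cc(1,2)")],
        ),
        modules=frozenset({"graph"}),
        provenance="printed dependencies",
        expected={"arcs": [("NN", "proteins", "and"), ("CC", "and", "Tat"),
                           ("CC", "and", "Sp1")]},
    ))

    return cases


def case(name: str) -> FixtureCase:
    for c in builtin_cases():
        if c.name == name:
            return c
    raise KeyError(name)


# -----------------------------------------------------------------------------
# random embedding trees with a brute-force composition oracle


_RANDOM_ENTRIES = [
    TriggerEntry("cause", "VB", "CAUSAL", "positive", 1.0, False),
    TriggerEntry("block", "VB", "CAUSAL", "negative", 1.0, False),
    TriggerEntry("link", "VB", "CORRELATIVE", "neutral", 0.5, False),
    TriggerEntry("may", "MD", "SPECULATIVE", "positive", 0.7, False),
    TriggerEntry("prove", "VB", "DEMONSTRATIVE", "positive", 1.0, False),
    TriggerEntry("fail", "VB", "SUCCESS", "negative", 1.0, False),
    TriggerEntry("not", "RB", "NEGATOR", "negative", 1.0, False),
    TriggerEntry("hardly", "RB", "DIMINISHER", "neutral", 0.6, False),
    TriggerEntry("strongly", "RB", "INTENSIFIER", "neutral", 0.8, False),
    TriggerEntry("express", "VB", "GENE_EXPRESSION", "neutral", 1.0, False),
    TriggerEntry("modify", "VB", "PHOSPHORYLATION", "neutral", 1.0, False),
]
_RANDOM_LABELS = ["DOBJ", "NSUBJ", "PREP_OF", "NN", "NEG", "AUX",
                  "PREP_AFTER", "PREP_IN", "ADVMOD", "XCOMP"]


def random_graph(seed: int, n_nodes: int = 8) -> EmbeddingGraph:
    """A random embedding tree of bound/free nodes with rule-matching arcs.

    Trees (single parent per node) keep operator application order
    unambiguous, so the brute-force oracle is well defined.
    """
    if n_nodes > 12:
        raise ValueError("random graphs are capped at 12 nodes")
    rng = random.Random(seed)
    graph = EmbeddingGraph()
    ids = []
    for i in range(n_nodes):
        roll = rng.random()
        if roll < 0.30:
            binding, obj, pos = "entity", EntityMention(
                id=f"T{i}", semantic_type="Protein",
                char_span=(i * 10, i * 10 + 5), text=f"ent{i}"), "NN"
        elif roll < 0.78:
            entry = rng.choice(_RANDOM_ENTRIES)
            binding, obj, pos = "predicate", entry, entry.pos
        else:
            binding, obj, pos = "free", None, rng.choice(["NN", "IN", "DT"])
        el = SurfaceElement(
            id=f"n{i}", tokens=(i + 1,), char_span=(i * 10, i * 10 + 5),
            sentence_index=0, text=f"w{i}",
            lemma=(obj.lemma if binding == "predicate" else f"w{i}"),
            pos=pos, binding=binding, bound_object=obj)
        graph.add_element(el)
        ids.append(el.id)
    for i in range(1, n_nodes):
        parent = ids[rng.randrange(i)]
        graph.add_relation(rng.choice(_RANDOM_LABELS), parent, ids[i])
    return graph


@dataclass(frozen=True)
class OraclePredication:
    """Comparable summary of one composed predication."""

    node: str
    semantic_type: str
    mv: float
    polarity: str
    args: tuple[tuple[str, str], ...]     # (arg_type, referent id)
    negated: bool


def oracle_compose(graph: EmbeddingGraph, rules: list[ArgumentRule],
                   config: Optional[CompositionConfig] = None
                   ) -> set[OraclePredication]:
    """Direct recursive evaluator of the composition definitions on a tree.

    Independent of the production composer: a plain post-order recursion over
    the tree, with argument propagation done by exhaustive enumeration of
    free-node paths.  Assumes at most one parent per node and no
    negative-raising triggers (the random generator guarantees both).
    """
    config = config or CompositionConfig()
    nodes = {el.id: el for el in graph.elements()}

    def children(n):
        return [(t, c) for t, c in graph.out_arcs(n)]

    # exhaustive free-path enumeration for argument propagation
    def free_paths(start):
        results = []

        def walk(n, d):
            if config.propagation_depth is not None and d > config.propagation_depth:
                return
            for _, c in children(n):
                if nodes[c].is_bound:
                    results.append((d, nodes[c].char_span, c))
                else:
                    walk(c, d + 1)

        walk(start, 1)
        return sorted(results)

    def find_args(nid):
        el = nodes[nid]
        assigned, taken = [], set()
        for rel_type, child in children(nid):
            rule = next((r for r in rules if rule_applies(r, el, rel_type)), None)
            if rule is None:
                continue
            if rule.arg_type in (OBJECT, SUBJECT) and rule.arg_type in taken:
                continue
            if nodes[child].is_bound:
                ref = child
            else:
                hits = free_paths(child)
                ref = hits[0][2] if hits else child
            if rule.arg_type in (OBJECT, SUBJECT):
                taken.add(rule.arg_type)
            assigned.append((rule.arg_type, ref))
        rank = {OBJECT: 0, SUBJECT: 1, ADJUNCT: 2}
        return sorted(assigned, key=lambda a: rank[a[0]])

    def scale_fn(entry: TriggerEntry) -> Callable[[float], float]:
        s = entry.category_strength
        if entry.semantic_type == "INTENSIFIER":
            return lambda mv: mv + (1 - s) * (1 - mv) if mv >= 0.5 else s * mv
        # MODAL and DIMINISHER share the rescaling law
        return lambda mv: s * mv if mv >= 0.5 else mv + (1 - s) * (1 - mv)

    # state per predicate node: [mv, polarity, negated]
    state: dict[str, list] = {}
    args_of: dict[str, list[tuple[str, str]]] = {}

    def invert(ref):
        st = state[ref]
        st[0] = 1.0 - st[0]
        st[1] = NEGATIVE
        st[2] = True

    def contents_of(nid):
        """Nearest non-operator predications reachable through argument
        positions, skipping operator predications."""
        out, queue = [], [r for _, r in args_of[nid] if r in state]
        while queue:
            ref = queue.pop(0)
            if is_operator_type(nodes[ref].bound_object.semantic_type):
                queue.extend(r for _, r in args_of[ref] if r in state)
            else:
                out.append(ref)
        return out

    def eval_node(nid):
        for _, c in children(nid):
            eval_node(c)
        el = nodes[nid]
        if not el.is_predicate:
            return
        entry: TriggerEntry = el.bound_object
        args = find_args(nid)
        args_of[nid] = args
        state[nid] = [config.default_mv, entry.polarity, False]
        pred_args = [r for _, r in args if r in state]
        obj = next((r for t, r in args if t == OBJECT and r in state), None)
        emb = obj if obj is not None else (pred_args[0] if pred_args else None)
        if emb is not None:
            state[nid][1] = compose_polarity(entry.polarity, state[emb][1])
        if entry.semantic_type == "NEGATOR":
            if not pred_args:
                state[nid][0] = 1.0 - state[nid][0]
                state[nid][2] = True
            else:
                for ref in pred_args:       # inverts its direct arguments
                    invert(ref)
                state[nid][0] = state[pred_args[0]][0]
        elif is_operator_type(entry.semantic_type):
            fn = scale_fn(entry)
            targets = contents_of(nid)
            if not targets:
                state[nid][0] = fn(state[nid][0])
            else:
                for ref in targets:
                    state[ref][0] = fn(state[ref][0])
                state[nid][0] = state[targets[0]][0]

    roots = [el.id for el in graph.elements()
             if not any(True for _ in graph.in_arcs(el.id))]
    for root in roots:
        eval_node(root)

    out = set()
    for nid, (mv, pol, neg) in state.items():
        args = tuple(
            (t, nodes[ref].bound_object.id if nodes[ref].is_entity else ref)
            for t, ref in args_of[nid])
        out.add(OraclePredication(
            node=nid, semantic_type=nodes[nid].bound_object.semantic_type,
            mv=round(mv, 9), polarity=pol, args=args, negated=neg))
    return out


def summarize_predications(preds) -> set[OraclePredication]:
    """Project composer output onto the oracle's comparable form."""
    out = set()
    for p in preds:
        args = []
        for a in p.args:
            v = a.value
            if hasattr(v, "predicate"):          # a Predication
                args.append((a.arg_type, v.predicate.id))
            else:                                # entity or free element
                args.append((a.arg_type, v.id))
        out.add(OraclePredication(
            node=p.predicate.id, semantic_type=p.semantic_type,
            mv=round(p.mv, 9), polarity=p.polarity,
            args=tuple(args), negated=p.negated))
    return out
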