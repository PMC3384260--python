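import pytest

from biocompose.compose import CompositionConfig, compose_document
from biocompose.coref import CompatibilityLexicons, resolve_all
from biocompose.fixtures import builtin_cases, case
from biocompose.graph import build_document_graph
from biocompose.standoff import (
    PipelineConfig, align_tokens, default_argument_rules, default_lexicon,
    process_document, write_a2,
)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def arg_rules():
    return default_argument_rules()


@pytest.fixture(scope="session")
def cases():
    return {c.name: c for c in builtin_cases()}


def build_case_graph(name, lexicon, coref=True):
    """Aligned document graph for a named fixture, optionally with COREF arcs."""
    c = case(name)
    sents = align_tokens(c.doc.text, c.doc.sentences)
    graph = build_document_graph(sents, c.doc.entities, lexicon)
    if coref:
        resolve_all(graph, c.compat or CompatibilityLexicons(),
                    paragraph_of=c.doc.paragraph_of())
    return c, graph


def compose_case(name, lexicon, arg_rules, coref=True, depth=None):
    c, graph = build_case_graph(name, lexicon, coref=coref)
    preds = compose_document(graph, arg_rules,
                             CompositionConfig(propagation_depth=depth))
    return c, graph, preds


def run_case(name, **overrides):
    """Full pipeline for a named fixture; returns (case, result, a2 text)."""
    c = case(name)
    cfg = PipelineConfig(track=c.track, compat=c.compat, **overrides)
    res = process_document(c.doc, cfg)
    return c, res, write_a2(res.events, res.modifications, c.doc.max_t_index)


def preds_by_lemma(preds):
    """Group composed predications by their trigger lemma."""
    out = {}
    for p in preds:
        out.setdefault(p.predicate.lemma, []).append(p)
    return out
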