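"""From syntactic dependencies to a document-level semantic embedding graph.

Per sentence, transformation rules turn collapsed typed dependencies (with
conjunct propagation) plus entity and trigger mentions into typed embedding
relations over surface elements.  Four rule classes are implemented —
corrective rewriting of modifier coordination, mention collapse, coordination
split, and direction inversion — plus an identity rule that uppercases any
dependency already isomorphic to an embedding relation.  The engine is
data-driven: each rule is a (name, action, params) record dispatched to an
action function, so further rules are configuration, not code.

Adjacent sentences are linked with PREV arcs between their topmost nodes;
coreference later adds COREF arcs.  Both special arc types may cross
sentences; everything else is intra-sentential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .lexicon import Lexicon, TriggerMention, match_triggers
from .model import ENTITY, FREE, PREDICATE, EntityMention, SurfaceElement

log = logging.getLogger(__name__)

SPECIAL_ARCS = {"PREV", "COREF"}


@dataclass(frozen=True)
class Token:
    index: int                  # 1-based within sentence
    form: str
    lemma: str = ""
    pos: str = ""
    char_span: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if not self.lemma:
            object.__setattr__(self, "lemma", self.form.lower())


@dataclass(frozen=True)
class SyntacticDependency:
    label: str
    governor: int               # 1-based token index
    dependent: int

    def __post_init__(self):
        if not self.label:
            raise ValueError("empty dependency label")


@dataclass
class ParsedSentence:
    tokens: list[Token]
    deps: list[SyntacticDependency]
    index: int = 0
    paragraph: int = 0

    def token(self, i: int) -> Token:
        for t in self.tokens:
            if t.index == i:
                return t
        raise KeyError(f"no token {i} in sentence {self.index}")


@dataclass(frozen=True)
class TransformationRule:
    """A named rewrite over the remaining dependency pool.

    ``action`` selects one of the registered engine actions; ``params``
    parameterise it (label sets, prefixes).  Rules apply in list order.
    """

    name: str
    action: str                 # corrective | collapse | split | invert | identity
    params: tuple = ()


def default_rules() -> list[TransformationRule]:
    """Core rule set, in priority order: corrections must precede consumers."""
    return [
        TransformationRule("modifier-coordination-correction", "corrective"),
        TransformationRule("np-internal-collapse", "collapse"),
        TransformationRule("coordination-split", "split", ("conj_",)),
        TransformationRule(
            "direction-inversion", "invert",
            ("amod", "advmod", "aux", "auxpass", "neg", "det", "partmod", "mark"),
        ),
        TransformationRule("identity-uppercase", "identity"),
    ]


class EmbeddingGraph:
    """Directed acyclic graph of surface elements with typed embedding arcs."""

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        self._arcs: list[tuple[str, str, str]] = []   # insertion order matters
        self.sentence_roots: list[str] = []

    # -- construction ---------------------------------------------------------
    def add_element(self, el: SurfaceElement) -> SurfaceElement:
        self._g.add_node(el.id, element=el)
        return el

    def add_relation(self, rel_type: str, source: str, target: str) -> bool:
        """Add a typed arc; duplicates are ignored.  Returns True if added."""
        rel_type = rel_type.upper()
        if source == target:
            return False
        if (rel_type, source, target) in self._arcs:
            return False
        self._g.add_edge(source, target, type=rel_type)
        self._arcs.append((rel_type, source, target))
        return True

    def remove_relation(self, rel_type: str, source: str, target: str) -> None:
        for src, tgt, key, data in list(self._g.edges(keys=True, data=True)):
            if src == source and tgt == target and data["type"] == rel_type:
                self._g.remove_edge(src, tgt, key)
        self._arcs = [a for a in self._arcs if a != (rel_type, source, target)]

    # -- queries --------------------------------------------------------------
    def element(self, node_id: str) -> SurfaceElement:
        return self._g.nodes[node_id]["element"]

    def has_node(self, node_id: str) -> bool:
        return node_id in self._g

    def elements(self) -> list[SurfaceElement]:
        return [self._g.nodes[n]["element"] for n in self._g.nodes]

    def arcs(self, types: Optional[set[str]] = None) -> list[tuple[str, str, str]]:
        if types is None:
            return list(self._arcs)
        return [a for a in self._arcs if a[0] in types]

    def out_arcs(self, node_id: str, exclude_special: bool = True):
        for rel_type, src, tgt in self._arcs:
            if src != node_id:
                continue
            if exclude_special and rel_type in SPECIAL_ARCS:
                continue
            yield rel_type, tgt

    def in_arcs(self, node_id: str, exclude_special: bool = True):
        for rel_type, src, tgt in self._arcs:
            if tgt != node_id:
                continue
            if exclude_special and rel_type in SPECIAL_ARCS:
                continue
            yield rel_type, src

    def coref_targets(self, node_id: str) -> list[str]:
        return [tgt for t, src, tgt in self._arcs
                if t == "COREF" and src == node_id]

    def nodes_of_sentence(self, sentence_index: int) -> list[SurfaceElement]:
        return [el for el in self.elements() if el.sentence_index == sentence_index]

    def core_view(self) -> nx.MultiDiGraph:
        """The graph without COREF arcs (the part required to be acyclic)."""
        view = nx.MultiDiGraph()
        view.add_nodes_from(self._g.nodes(data=True))
        for src, tgt, data in self._g.edges(data=True):
            if data["type"] != "COREF":
                view.add_edge(src, tgt, **data)
        return view

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.core_view())

    def undirected_distance(self, a: str, b: str) -> Optional[int]:
        """Shortest path length over intra-sentential + PREV arcs."""
        und = self.core_view().to_undirected(as_view=False)
        try:
            return nx.shortest_path_length(und, a, b)
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            return None

    def merge(self, other: "EmbeddingGraph") -> None:
        for el in other.elements():
            self.add_element(el)
        for rel_type, src, tgt in other.arcs():
            self.add_relation(rel_type, src, tgt)
        self.sentence_roots.extend(other.sentence_roots)


# -----------------------------------------------------------------------------
# sentence-level construction


class _Workspace:
    """Mutable state threaded through the rule actions for one sentence."""

    def __init__(self, graph: EmbeddingGraph, sentence: ParsedSentence,
                 tok2el: dict[int, str], counter: list[int]):
        self.graph = graph
        self.sentence = sentence
        self.tok2el = tok2el
        self.pool: list[SyntacticDependency] = list(sentence.deps)
        self._counter = counter

    def new_id(self) -> str:
        self._counter[0] += 1
        return f"s{self.sentence.index}n{self._counter[0]}"

    def element_of(self, token_index: int) -> str:
        return self.tok2el[token_index]

    def consume(self, dep: SyntacticDependency) -> None:
        self.pool.remove(dep)

    def make_conjunction_node(self, near_token: int, lexeme: str) -> str:
        """Find the conjunction token (cc dependent) or synthesise a node."""
        cc_deps = [d for d in self.pool if d.label == "cc"]
        cc_deps.sort(key=lambda d: (d.governor != near_token, d.dependent))
        for dep in cc_deps:
            self.consume(dep)
            return self.element_of(dep.dependent)
        tok = self.sentence.token(near_token) if any(
            t.index == near_token for t in self.sentence.tokens) else None
        span = tok.char_span if tok and tok.char_span else (0, 0)
        el = SurfaceElement(
            id=self.new_id(), tokens=(near_token,), char_span=span or (0, 0),
            sentence_index=self.sentence.index, text=lexeme, lemma=lexeme,
            pos="CC", binding=FREE, virtual=True,
        )
        self.graph.add_element(el)
        return el.id


def _action_corrective(ws: _Workspace, rule: TransformationRule) -> None:
    """Modifier coordination: conj_X(A,H) with nn(H,M) -> NN(H,and)+CC(and,A)+CC(and,M)."""
    for dep in list(ws.pool):
        if not dep.label.startswith("conj_"):
            continue
        head = dep.dependent
        nn_deps = [d for d in ws.pool
                   if d.label == "nn" and d.governor == head
                   and ws.element_of(d.dependent) != ws.element_of(head)]
        if not nn_deps:
            continue
        lexeme = dep.label.split("_", 1)[1]
        conj = ws.make_conjunction_node(dep.governor, lexeme)
        ws.graph.add_relation("NN", ws.element_of(head), conj)
        ws.graph.add_relation("CC", conj, ws.element_of(dep.governor))
        for nn in nn_deps:
            ws.graph.add_relation("CC", conj, ws.element_of(nn.dependent))
            ws.consume(nn)
        ws.consume(dep)


def _action_collapse(ws: _Workspace, rule: TransformationRule) -> None:
    """Mention collapse happened at binding time; here drop intra-unit deps."""
    for dep in list(ws.pool):
        if ws.element_of(dep.governor) == ws.element_of(dep.dependent):
            ws.consume(dep)


def _action_split(ws: _Workspace, rule: TransformationRule) -> None:
    """conj_X(A,B),conj_X(A,C) -> CC(x,A)+CC(x,B)+CC(x,C) around one x node."""
    prefix = rule.params[0] if rule.params else "conj_"
    groups: dict[tuple[str, str], list[SyntacticDependency]] = {}
    for dep in ws.pool:
        if dep.label.startswith(prefix):
            key = (ws.element_of(dep.governor), dep.label)
            groups.setdefault(key, []).append(dep)
    for (gov_el, label), deps in groups.items():
        lexeme = label[len(prefix):] or "and"
        conj = ws.make_conjunction_node(deps[0].governor, lexeme)
        ws.graph.add_relation("CC", conj, gov_el)
        for dep in deps:
            ws.graph.add_relation("CC", conj, ws.element_of(dep.dependent))
            ws.consume(dep)


def _action_invert(ws: _Workspace, rule: TransformationRule) -> None:
    """Chain trigger-bound modifiers above their head: d1 >s d2 >s ... >s head.

    Only dependents bound to embedding/atomic triggers invert; an unbound
    modifier (e.g. 'rapid') keeps the syntactic direction via the identity
    rule.  When several modifiers share a head they are chained in token
    order, reproducing e.g. Thus >s may >s not >s involve.
    """
    labels = set(rule.params)
    by_head: dict[int, list[SyntacticDependency]] = {}
    for dep in ws.pool:
        if dep.label in labels:
            el = ws.graph.element(ws.element_of(dep.dependent))
            if el.is_predicate:
                by_head.setdefault(dep.governor, []).append(dep)
    for head, deps in by_head.items():
        chain = sorted(deps, key=lambda d: d.dependent)
        nodes = [ws.element_of(d.dependent) for d in chain] + [ws.element_of(head)]
        for dep, src, tgt in zip(chain, nodes, nodes[1:]):
            ws.graph.add_relation(dep.label.upper(), src, tgt)
            ws.consume(dep)


def _action_identity(ws: _Workspace, rule: TransformationRule) -> None:
    for dep in list(ws.pool):
        src, tgt = ws.element_of(dep.governor), ws.element_of(dep.dependent)
        if src != tgt:
            ws.graph.add_relation(dep.label.upper(), src, tgt)
        ws.consume(dep)


_ACTIONS = {
    "corrective": _action_corrective,
    "collapse": _action_collapse,
    "split": _action_split,
    "invert": _action_invert,
    "identity": _action_identity,
}


def _mention_token_groups(sentence: ParsedSentence,
                          entities: Sequence[EntityMention],
                          triggers: Sequence[TriggerMention]):
    """Partition token indices into mention-bound groups; entities win overlaps."""
    groups: list[tuple[tuple[int, ...], str, object]] = []
    claimed: set[int] = set()
    for ent in entities:
        toks = tuple(
            t.index for t in sentence.tokens
            if t.char_span and t.char_span[0] < ent.char_span[1]
            and t.char_span[1] > ent.char_span[0]
        )
        if toks and not (set(toks) & claimed):
            groups.append((toks, ENTITY, ent))
            claimed |= set(toks)
    for trig in triggers:
        if not (set(trig.token_indices) & claimed):
            groups.append((trig.token_indices, PREDICATE, trig.entry))
            claimed |= set(trig.token_indices)
    return groups


def build_sentence_graph(sentence: ParsedSentence,
                         entities: Sequence[EntityMention] = (),
                         lexicon: Optional[Lexicon] = None,
                         rules: Optional[list[TransformationRule]] = None,
                         _counter: Optional[list[int]] = None) -> EmbeddingGraph:
    """Build the intra-sentential embedding subgraph for one parsed sentence."""
    rules = default_rules() if rules is None else rules
    counter = _counter if _counter is not None else [0]
    graph = EmbeddingGraph()

    triggers = match_triggers(sentence.tokens, lexicon) if lexicon else []
    groups = _mention_token_groups(sentence, entities, triggers)

    tok2el: dict[int, str] = {}
    bound_groups = {}
    for toks, binding, obj in groups:
        bound_groups[toks] = (binding, obj)

    def make_element(toks: tuple[int, ...], binding: str, obj) -> SurfaceElement:
        counter[0] += 1
        members = [sentence.token(i) for i in toks]
        spans = [t.char_span for t in members if t.char_span]
        char_span = (min(s[0] for s in spans), max(s[1] for s in spans)) if spans else (0, 0)
        head = members[-1]
        el = SurfaceElement(
            id=f"s{sentence.index}n{counter[0]}",
            tokens=toks, char_span=char_span, sentence_index=sentence.index,
            text=" ".join(t.form for t in members),
            lemma=(obj.lemma if binding == PREDICATE
                   else " ".join(t.lemma for t in members)),
            pos=head.pos, binding=binding, bound_object=obj,
        )
        return el

    for toks, (binding, obj) in bound_groups.items():
        el = graph.add_element(make_element(toks, binding, obj))
        for i in toks:
            tok2el[i] = el.id
    for tok in sentence.tokens:
        if tok.index not in tok2el:
            el = graph.add_element(make_element((tok.index,), FREE, None))
            tok2el[tok.index] = el.id

    ws = _Workspace(graph, sentence, tok2el, counter)
    for rule in rules:
        action = _ACTIONS.get(rule.action)
        if action is None:
            raise ValueError(f"unknown transformation action {rule.action!r}")
        action(ws, rule)

    _break_cycles(graph)
    root = topmost(graph, sentence.index)
    if root is not None:
        graph.sentence_roots.append(root)
    return graph


def _break_cycles(graph: EmbeddingGraph) -> None:
    """Drop the cycle arc whose target has the latest char offset, until a DAG."""
    while not graph.is_acyclic():
        cycle = nx.find_cycle(graph.core_view())
        worst = max(cycle, key=lambda e: graph.element(e[1]).char_span)
        src, tgt = worst[0], worst[1]
        rel_type = next(t for t, s, g in graph.arcs() if s == src and g == tgt)
        log.warning("breaking cycle: dropping %s(%s,%s)", rel_type, src, tgt)
        graph.remove_relation(rel_type, src, tgt)


def topmost(graph: EmbeddingGraph, sentence_index: int) -> Optional[str]:
    """The unique node of a sentence with no incoming intra-sentential arc.

    Ties (a forest) break to the earliest character offset.
    """
    nodes = graph.nodes_of_sentence(sentence_index)
    if not nodes:
        return None
    has_incoming = set()
    for rel_type, src, tgt in graph.arcs():
        if rel_type in SPECIAL_ARCS:
            continue
        if graph.element(src).sentence_index == sentence_index:
            has_incoming.add(tgt)
    roots = [el for el in nodes if el.id not in has_incoming]
    pool = roots or nodes
    # isolated stray tokens (no arcs at all) must not outrank the real root
    has_outgoing = {src for t, src, _ in graph.arcs() if t not in SPECIAL_ARCS}
    connected = [el for el in pool if el.id in has_outgoing or el.id in has_incoming]
    pool = connected or pool
    return min(pool, key=lambda el: (el.char_span, el.id)).id


def link_sentences(subgraphs: Iterable[EmbeddingGraph]) -> EmbeddingGraph:
    """Merge sentence subgraphs and add PREV arcs between adjacent roots."""
    doc = EmbeddingGraph()
    for sub in subgraphs:
        doc.merge(sub)
    for a, b in zip(doc.sentence_roots, doc.sentence_roots[1:]):
        doc.add_relation("PREV", a, b)
    return doc


def build_document_graph(sentences: Sequence[ParsedSentence],
                         entities: Sequence[EntityMention] = (),
                         lexicon: Optional[Lexicon] = None,
                         rules: Optional[list[TransformationRule]] = None) -> EmbeddingGraph:
    """Convenience wrapper: per-sentence graphs + PREV links in one call."""
    counter = [0]
    subs = []
    for sent in sentences:
        sent_entities = [
            e for e in entities
            if any(t.char_span and t.char_span[0] < e.char_span[1]
                   and t.char_span[1] > e.char_span[0] for t in sent.tokens)
        ]
        subs.append(build_sentence_graph(sent, sent_entities, lexicon, rules,
                                         _counter=counter))
    return link_sentences(subs)
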