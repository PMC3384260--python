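"""Bottom-up predication composition over the embedding graph.

Processing order is reverse-topological (children before parents), so inner
operators apply before outer ones: in ``may >s not >s involve`` the negator
inverts the modality value of the *involve* predication (1 -> 0) before the
speculative modal rescales it (0 -> 0.3 at category strength 0.7).

The calculus:

* polarity composition — a neutral trigger passes the embedded polarity
  through, a negative trigger is absorbing, and a positive trigger yields
  negative iff the embedded polarity is negative;
* modality value composition — a NEGATOR inverts mv (1 - mv); a MODAL with
  strength s maps mv >= 0.5 to s*mv and mv < 0.5 to mv + (1-s)(1-mv);
  DIMINISHER behaves like a modal, INTENSIFIER swaps the two branches;
* argument propagation — a bound descendant may serve as argument when every
  intervening node is semantically free (optionally depth-limited);
* coordination distribution and anaphor substitution — a slot resolving to a
  conjunction or to a plural anaphor's antecedents yields one predication per
  value, all other slots shared;
* negative raising — negation on a raising predicate (think, believe)
  transfers to its complement.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import networkx as nx

from .graph import EmbeddingGraph
from .lexicon import TriggerEntry, coarse_pos
from .model import (
    ADJUNCT, NEGATIVE, NEUTRAL, OBJECT, SUBJECT,
    Argument, ArgValue, CycleError, Predication, SurfaceElement,
    category_of, is_operator_type, sort_args,
)

# -----------------------------------------------------------------------------
# argument identification rules


@dataclass(frozen=True)
class ArgumentRule:
    """Typed rule <relation type, POS, inclusions, exclusions> -> argument type.

    A predicate satisfies a constraint set when its lemma or its semantic type
    is a member.  The rule applies when the relation type matches, the
    predicate's coarse POS matches (``-`` or an empty predicate POS acts as a
    wildcard), the inclusion list is empty or satisfied, and the exclusion
    list is not satisfied.
    """

    relation_type: str
    pos: str
    inclusions: frozenset[str] = frozenset()
    exclusions: frozenset[str] = frozenset()
    arg_type: str = ADJUNCT

    def __post_init__(self):
        if self.arg_type not in (OBJECT, SUBJECT, ADJUNCT):
            raise ValueError(f"bad argument type {self.arg_type!r}")
        if self.inclusions & self.exclusions:
            raise ValueError("inclusions and exclusions overlap")


def _satisfies(element: SurfaceElement, constraint: frozenset[str]) -> bool:
    if element.lemma.lower() in constraint:
        return True
    entry = element.bound_object
    if isinstance(entry, TriggerEntry) and entry.semantic_type in constraint:
        return True
    return False


def rule_applies(rule: ArgumentRule, predicate: SurfaceElement, rel_type: str) -> bool:
    if rule.relation_type != rel_type:
        return False
    if rule.pos not in ("", "-") and predicate.pos and coarse_pos(predicate.pos) != rule.pos:
        return False
    if rule.inclusions and not _satisfies(predicate, rule.inclusions):
        return False
    if _satisfies(predicate, rule.exclusions):
        return False
    return True


def identify_arguments(node_id: str, graph: EmbeddingGraph,
                       rules: list[ArgumentRule]) -> list[tuple[str, str, str]]:
    """Assign logical argument types to a predicate node's outgoing relations.

    Returns (arg_type, relation_type, child_node_id) triples.  The first rule
    in file order that applies wins per relation; at most one Object and one
    Subject are assigned per predication (first assignment wins).
    """
    predicate = graph.element(node_id)
    out: list[tuple[str, str, str]] = []
    taken: set[str] = set()
    for rel_type, child in graph.out_arcs(node_id):
        for rule in rules:
            if rule_applies(rule, predicate, rel_type):
                if rule.arg_type in (OBJECT, SUBJECT) and rule.arg_type in taken:
                    break
                if rule.arg_type in (OBJECT, SUBJECT):
                    taken.add(rule.arg_type)
                out.append((rule.arg_type, rel_type, child))
                break
    return out


def load_argument_rules(source: Union[str, os.PathLike, Iterable[str]]) -> list[ArgumentRule]:
    """Read the 5-column rule TSV: relation, POS, inclusions, exclusions, type."""
    if isinstance(source, (str, os.PathLike)):
        with open(source, encoding="utf-8") as fh:
            return load_argument_rules(list(fh))
    rules = []
    for lineno, raw in enumerate(source, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = [c.strip() for c in line.split("\t")]
        if len(cols) != 5:
            raise ValueError(f"argument rule line {lineno}: expected 5 columns")
        def parse_set(col: str) -> frozenset[str]:
            if col in ("-", ""):
                return frozenset()
            return frozenset(x.strip().lower() if not x.strip().isupper() else x.strip()
                             for x in col.split(","))
        rules.append(ArgumentRule(
            relation_type=cols[0].upper(),
            pos=cols[1].upper() if cols[1] not in ("-", "") else "-",
            inclusions=parse_set(cols[2]),
            exclusions=parse_set(cols[3]),
            arg_type=cols[4],
        ))
    return rules


# -----------------------------------------------------------------------------
# scalar operators


def compose_polarity(trigger_polarity: str, embedded_polarity: str) -> str:
    """Polarity composition: neutral passes through, negative absorbs,
    positive flips to negative only over a negative embedded value."""
    if trigger_polarity == NEUTRAL:
        return embedded_polarity
    if trigger_polarity == NEGATIVE:
        return NEGATIVE
    return NEGATIVE if embedded_polarity == NEGATIVE else "positive"


def _clamp(mv: float) -> float:
    return min(1.0, max(0.0, mv))


def apply_negator(mv: float) -> float:
    """Invert a modality value with respect to the [0, 1] range."""
    return _clamp(1.0 - mv)


def apply_modal(strength: float, mv: float) -> float:
    """Rescale mv proportionally to category strength.

    A modal lowers values initially closer to 1 (s * mv) and raises values in
    a negative context (mv + (1-s)(1-mv)), so 'may' at strength 0.7 maps
    1 -> 0.7 and 0 -> 0.3.
    """
    if mv >= 0.5:
        return _clamp(strength * mv)
    return _clamp(mv + (1.0 - strength) * (1.0 - mv))


def apply_diminisher_intensifier(entry: TriggerEntry, mv: float) -> float:
    """Valence shifters rescale mv like modals; an intensifier swaps branches
    (pushing values outward) while a diminisher pulls them inward."""
    s = entry.category_strength
    if entry.semantic_type == "DIMINISHER":
        return apply_modal(s, mv)
    if entry.semantic_type == "INTENSIFIER":
        if mv >= 0.5:
            return _clamp(mv + (1.0 - s) * (1.0 - mv))
        return _clamp(s * mv)
    raise ValueError(f"not a diminisher/intensifier: {entry.semantic_type}")


def propagate_arguments(free_node: str, graph: EmbeddingGraph,
                        depth: Optional[int] = None) -> list[str]:
    """Bound argument candidates reachable from a free node through chains of
    semantically free nodes.

    Depth counts the free nodes on the path (the licensed child included).
    Candidates are ordered closest-first, ties broken by earlier character
    offset; conjunction nodes and resolved anaphors count as bound targets.
    """
    found: list[tuple[int, tuple, str]] = []
    queue = [(free_node, 1)]
    visited = {free_node}
    while queue:
        node, d = queue.pop(0)       # breadth-first: first visit is minimal depth
        if depth is not None and d > depth:
            continue
        for _, child in graph.out_arcs(node):
            if child in visited:
                continue
            visited.add(child)
            cel = graph.element(child)
            is_conj = any(t == "CC" for t, _ in graph.out_arcs(child))
            if cel.is_bound or is_conj or graph.coref_targets(child):
                found.append((d, cel.char_span, child))
            else:
                queue.append((child, d + 1))
    return [node for _, _, node in sorted(found)]


# -----------------------------------------------------------------------------
# document composition


@dataclass
class CompositionConfig:
    propagation_depth: Optional[int] = None     # None = unlimited
    default_mv: float = 1.0
    coordination_labels: frozenset[str] = frozenset({"CC"})

    def __post_init__(self):
        if self.propagation_depth is not None and self.propagation_depth < 1:
            raise ValueError("propagation depth must be >= 1 when finite")


@dataclass(frozen=True)
class _Pending:
    """Forward reference to a predication not yet composed.

    Arises when an anaphor's antecedent is a predicate node that structurally
    dominates the anaphor's consumer (relative clauses: the matrix noun
    embeds the clause, while the relative pronoun points back at it).
    Patched in after the traversal completes.
    """

    node_id: str


class _Composer:
    def __init__(self, graph: EmbeddingGraph, rules: list[ArgumentRule],
                 config: CompositionConfig):
        self.graph = graph
        self.rules = rules
        self.config = config
        self.node_preds: dict[str, list[Predication]] = {}
        self.created: list[Predication] = []
        self._n = 0

    # -- resolution -----------------------------------------------------------
    def is_conjunction(self, node_id: str) -> bool:
        return any(t == "CC" for t, _ in self.graph.out_arcs(node_id))

    def resolve(self, node_id: str, allow_propagation: bool = True,
                _seen: frozenset = frozenset()) -> list[ArgValue]:
        """Resolve a child node to argument values (entities, free elements or
        predications); a multi-element result signals distribution."""
        if node_id in _seen:
            return []
        seen = _seen | {node_id}
        el = self.graph.element(node_id)
        coref = self.graph.coref_targets(node_id)
        if coref:
            vals: list[ArgValue] = []
            for tgt in sorted(coref, key=lambda n: (
                    self.graph.element(n).sentence_index,
                    self.graph.element(n).char_span)):
                vals.extend(self.resolve(tgt, allow_propagation=False, _seen=seen))
            if vals:
                return vals
        if self.is_conjunction(node_id):
            vals = []
            for t, tgt in self.graph.out_arcs(node_id):
                if t == "CC":
                    vals.extend(self.resolve(tgt, allow_propagation=False, _seen=seen))
            return vals
        if el.is_entity:
            return [el.bound_object]
        if el.is_predicate:
            preds = self.node_preds.get(node_id)
            if preds is None:
                return [_Pending(node_id)]
            return list(preds)
        if allow_propagation:
            found = self.propagate(node_id)
            if found is not None:
                return self.resolve(found, allow_propagation=False, _seen=seen)
        return [el]      # a semantically free element, kept as unknown entity

    def propagate(self, free_node: str) -> Optional[str]:
        cands = propagate_arguments(free_node, self.graph,
                                    self.config.propagation_depth)
        return cands[0] if cands else None

    # -- composition ----------------------------------------------------------
    def compose_node(self, node_id: str) -> None:
        el = self.graph.element(node_id)
        if not el.is_predicate:
            return
        entry: TriggerEntry = el.bound_object
        assignments = identify_arguments(node_id, self.graph, self.rules)

        slot_values: list[tuple[str, list[ArgValue]]] = []
        for arg_type, _rel, child in assignments:
            values = self.resolve(child)
            if values:
                slot_values.append((arg_type, values))

        variants = self._distribute(slot_values)
        preds = []
        for args in variants:
            self._n += 1
            pred = Predication(
                id=f"tmp{self._n}", predicate=el,
                semantic_type=entry.semantic_type,
                mv=self.config.default_mv,
                polarity=entry.polarity,
                args=sort_args(args),
            )
            preds.append(pred)
            self.created.append(pred)
        self.node_preds[node_id] = preds

        for pred in preds:
            self._apply_polarity(pred, entry)
        cat = category_of(entry.semantic_type)
        if entry.semantic_type == "NEGATOR":
            for pred in preds:
                self._percolate_negator(pred)
        elif cat == "MODAL":
            for pred in preds:
                self._percolate_scale(pred, lambda mv: apply_modal(entry.category_strength, mv))
        elif entry.semantic_type in ("DIMINISHER", "INTENSIFIER"):
            for pred in preds:
                self._percolate_scale(pred, lambda mv: apply_diminisher_intensifier(entry, mv))
        elif cat == "ATTRIBUTIVE":
            for pred in preds:
                self._attributive_transfer(pred, entry)

    _ATTR_SLOT = {"PATIENT": OBJECT, "AGENTIVE": SUBJECT, "EXPERIENCER": SUBJECT}

    def _attributive_transfer(self, pred: Predication, entry: TriggerEntry) -> None:
        """An attributive predicate links its own simple argument into the
        predication it embeds, in the role named by its semantic type
        (p105 undergoes degradation => degradation(p105))."""
        slot = self._ATTR_SLOT[entry.semantic_type]
        emb = next((a.value for a in pred.args if isinstance(a.value, Predication)), None)
        donor = next((a.value for a in pred.args
                      if not isinstance(a.value, Predication)), None)
        if emb is None or donor is None:
            return
        if not any(a.arg_type == slot for a in emb.args):
            emb.args = sort_args(emb.args + [Argument(slot, donor)])

    def _distribute(self, slot_values) -> list[list[Argument]]:
        """Cartesian distribution over multi-valued Object/Subject slots;
        multi-valued adjunct slots flatten into several adjunct arguments."""
        variants: list[list[Argument]] = [[]]
        for arg_type, values in slot_values:
            if arg_type == ADJUNCT:
                for v in variants:
                    v.extend(Argument(ADJUNCT, val) for val in values)
            else:
                variants = [v + [Argument(arg_type, val)]
                            for v in variants for val in values]
        return variants

    def _apply_polarity(self, pred: Predication, entry: TriggerEntry) -> None:
        emb = pred.object if isinstance(pred.object, Predication) else None
        if emb is None:
            inner = pred.predication_args
            emb = inner[0] if inner else None
        if emb is not None:
            pred.polarity = compose_polarity(entry.polarity, emb.polarity)

    def _content_targets(self, pred: Predication) -> list[Predication]:
        """Nearest non-operator predications in scope (operators are skipped)."""
        out, queue, seen = [], list(pred.predication_args), set()
        while queue:
            p = queue.pop(0)
            if p.id in seen:
                continue
            seen.add(p.id)
            if is_operator_type(p.semantic_type):
                queue.extend(p.predication_args)
            else:
                out.append(p)
        return out

    def _percolate_scale(self, pred: Predication, fn) -> None:
        targets = self._content_targets(pred)
        if not targets:
            pred.mv = _clamp(fn(pred.mv))
            return
        for t in targets:
            t.mv = _clamp(fn(t.mv))
        pred.mv = targets[0].mv

    def _invert(self, target: Predication) -> None:
        target.mv = apply_negator(target.mv)
        target.negated = True
        target.polarity = compose_polarity(NEGATIVE, target.polarity)

    def _percolate_negator(self, pred: Predication) -> None:
        targets = pred.predication_args
        if not targets:
            pred.mv = apply_negator(pred.mv)
            pred.negated = True
            return
        final = []
        for t in targets:
            raised = apply_negative_raising_entry(t)
            if raised is not None:
                for sub in self._content_targets(t):
                    self._invert(sub)
                    final.append(sub)
            else:
                self._invert(t)
                final.append(t)
        if final:
            pred.mv = final[0].mv

    def _late_negators(self) -> None:
        """A negator with no predication argument (e.g. the determiner 'no')
        negates the nearest predication taking one of its descendants as an
        argument."""
        for node_id, preds in self.node_preds.items():
            el = self.graph.element(node_id)
            entry = el.bound_object
            if not (isinstance(entry, TriggerEntry) and entry.semantic_type == "NEGATOR"):
                continue
            if any(p.predication_args for p in preds):
                continue
            # descendants reachable without crossing another predicate node:
            # the negation attaches to whatever event takes those elements as
            # arguments (determiner negation), not to arbitrary predications
            desc_objs, queue, seen = set(), [node_id], {node_id}
            while queue:
                cur = queue.pop(0)
                for _, child in self.graph.out_arcs(cur):
                    if child in seen:
                        continue
                    seen.add(child)
                    delem = self.graph.element(child)
                    if delem.is_predicate:
                        continue
                    desc_objs.add(delem.id)
                    if delem.is_entity:
                        desc_objs.add(delem.bound_object.id)
                    else:
                        queue.append(child)
            hits = [p for p in self.created
                    if not is_operator_type(p.semantic_type)
                    and any(getattr(a.value, "id", None) in desc_objs for a in p.args)
                    and not p.negated]
            for hit in hits:
                self._invert(hit)


def apply_negative_raising_entry(pred: Predication) -> Optional[TriggerEntry]:
    """Return the trigger entry if this predication's predicate licenses
    negative raising (negation transfers to its complement), else None."""
    entry = pred.predicate.bound_object
    if isinstance(entry, TriggerEntry) and entry.negative_raising:
        return entry
    return None


def compose_document(graph: EmbeddingGraph, rules: list[ArgumentRule],
                     config: Optional[CompositionConfig] = None) -> list[Predication]:
    """Compose all predications of a document graph, bottom-up.

    Returns predications with deterministic ids assigned in document order
    (sentence, then predicate character offset).  Raises :class:`CycleError`
    if the non-COREF graph is cyclic.
    """
    config = config or CompositionConfig()
    core = graph.core_view()
    if not nx.is_directed_acyclic_graph(core):
        raise CycleError("embedding graph is cyclic")
    composer = _Composer(graph, rules, config)
    order = list(nx.lexicographical_topological_sort(
        core, key=lambda n: (graph.element(n).sentence_index,
                             graph.element(n).char_span, n)))
    for node in reversed(order):
        composer.compose_node(node)
    # patch forward references (anaphors whose antecedent predication was
    # composed after its consumer, e.g. relative clauses); scalar values are
    # not recomputed — the operators above the consumer have already applied
    for pred in composer.created:
        if not any(isinstance(a.value, _Pending) for a in pred.args):
            continue
        patched = []
        for arg in pred.args:
            if isinstance(arg.value, _Pending):
                repl = composer.node_preds.get(arg.value.node_id) or []
                if repl:
                    patched.append(Argument(arg.arg_type, repl[0]))
            else:
                patched.append(arg)
        pred.args = sort_args(patched)
    composer._late_negators()

    preds = sorted(
        composer.created,
        key=lambda p: (p.predicate.sentence_index, p.predicate.char_span,
                       composer.created.index(p)),
    )
    for i, pred in enumerate(preds, 1):
        pred.id = f"p{i}"
    return preds
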