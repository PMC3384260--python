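"""Deterministic coreference resolution over the embedding graph.

Four anaphora classes are handled:

* RELAT — relative pronouns; the antecedent is the head of the modified NP
  (REL(X, RP) together with RCMOD(ANT, X) yields COREF(RP, ANT));
* APPOS — appositive-family constructions (appos, abbrev, prep_including,
  prep_such_as), direction-normalised anaphor -> antecedent;
* PRON — third-person personal/possessive pronouns, resolved by person and
  number agreement;
* DNP — definite/demonstrative NPs not bound to entities (sortal anaphora),
  resolved by number agreement plus at least one semantic constraint: head
  word identity, singular/plural hypernymy, meronymy, or the event constraint
  (anaphor and antecedent lexicalise the same event).

Candidates are prior nodes in the anaphor's paragraph window that are
semantically bound, hypernym-headed, or conjunctions; structural blockers
remove candidates that directly embed / are embedded by the anaphor or that
stand in subject-object / subject-adjunct configurations of the same
relation.  The surviving candidate closest in the embedding graph (shortest
undirected path over intra-sentential + PREV arcs; ties broken by token
distance, then by earlier offset) is selected.  A plural anaphor resolving to
a conjunction receives one COREF arc per conjunct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .graph import EmbeddingGraph
from .lexicon import TriggerEntry
from .model import SurfaceElement

RELAT, PRON, DNP, APPOS = "RELAT", "PRON", "DNP", "APPOS"
ALL_CLASSES = frozenset({RELAT, PRON, DNP, APPOS})

APPOS_RELATIONS = {"APPOS", "ABBREV", "PREP_INCLUDING", "PREP_SUCH_AS"}
RELATIVE_PRONOUNS = {"which", "that", "who", "whom", "whose"}
PRON_SINGULAR = {"it", "its", "itself"}
PRON_PLURAL = {"they", "their", "them", "themselves"}
REFLEXIVE = {"itself", "themselves"}
DEFINITE_DETERMINERS = {"the", "this", "these", "that", "those"}

SUBJECT_ARCS = {"NSUBJ", "AGENT", "XSUBJ", "CSUBJ"}
OBJECT_ARCS = {"DOBJ", "NSUBJPASS", "OBJ", "IOBJ"}

DEFAULT_HYPERNYMS = frozenset({"gene", "protein", "factor", "cytokine"})
DEFAULT_MERONYMS = frozenset({"complex", "dimer", "subunit"})


@dataclass
class CompatibilityLexicons:
    """Head-noun lists backing the sortal-anaphora semantic constraints."""

    hypernyms: frozenset[str] = DEFAULT_HYPERNYMS
    meronyms: frozenset[str] = DEFAULT_MERONYMS

    def __post_init__(self):
        if not self.hypernyms or not self.meronyms:
            raise ValueError("compatibility lexicons must be non-empty")
        self.hypernyms = frozenset(w.lower() for w in self.hypernyms)
        self.meronyms = frozenset(w.lower() for w in self.meronyms)

    @classmethod
    def from_files(cls, hypernym_path: Optional[str] = None,
                   meronym_path: Optional[str] = None) -> "CompatibilityLexicons":
        def read(path, default):
            if path is None:
                return default
            with open(path, encoding="utf-8") as fh:
                words = frozenset(
                    line.strip().lower() for line in fh
                    if line.strip() and not line.startswith("#"))
            return words or default
        return cls(hypernyms=read(hypernym_path, DEFAULT_HYPERNYMS),
                   meronyms=read(meronym_path, DEFAULT_MERONYMS))


@dataclass(frozen=True)
class AnaphorMention:
    node: SurfaceElement
    klass: str
    number: Optional[str]           # singular | plural | None (unknown)
    person: int = 3
    reflexive: bool = False
    head_lemma: str = ""

    def __post_init__(self):
        if self.klass not in ALL_CLASSES:
            raise ValueError(f"unknown anaphora class {self.klass!r}")


# -----------------------------------------------------------------------------
# number / headedness helpers


def is_conjunction(graph: EmbeddingGraph, node_id: str) -> bool:
    return any(t == "CC" for t, _ in graph.out_arcs(node_id))


def number_of(graph: EmbeddingGraph, el: SurfaceElement) -> Optional[str]:
    """Grammatical number; None when undefined (e.g. verbal triggers)."""
    if is_conjunction(graph, el.id):
        return "plural"
    lemma = el.lemma.lower()
    if lemma in PRON_PLURAL:
        return "plural"
    if lemma in PRON_SINGULAR:
        return "singular"
    pos = el.pos
    if pos.startswith("NNS") or pos == "NNPS":
        return "plural"
    if pos.startswith("NN") or pos.startswith("PRP"):
        return "singular"
    if el.is_entity:
        return "singular"
    return None


def head_lemma(el: SurfaceElement) -> str:
    """Head of a (possibly collapsed) nominal: its last-token lemma."""
    return el.lemma.split()[-1].lower() if el.lemma else ""


# -----------------------------------------------------------------------------
# anaphor detection


def detect_anaphors(graph: EmbeddingGraph,
                    classes: frozenset[str] = ALL_CLASSES) -> list[AnaphorMention]:
    """Find PRON and DNP anaphoric mentions (RELAT/APPOS are rule-local)."""
    out: list[AnaphorMention] = []
    for el in sorted(graph.elements(), key=lambda e: (e.sentence_index, e.char_span)):
        lemma = el.lemma.lower()
        if PRON in classes and not el.is_bound and lemma in (PRON_SINGULAR | PRON_PLURAL):
            out.append(AnaphorMention(
                node=el, klass=PRON,
                number="plural" if lemma in PRON_PLURAL else "singular",
                reflexive=lemma in REFLEXIVE, head_lemma=lemma))
            continue
        if DNP in classes and not el.is_entity and not el.virtual:
            det = None
            for t, tgt in graph.out_arcs(el.id):
                if t == "DET" and graph.element(tgt).lemma.lower() in DEFINITE_DETERMINERS:
                    det = tgt
                    break
            if det is not None and (el.pos.startswith("NN") or not el.pos):
                out.append(AnaphorMention(
                    node=el, klass=DNP, number=number_of(graph, el),
                    head_lemma=head_lemma(el)))
    return out


# -----------------------------------------------------------------------------
# RELAT and APPOS


def resolve_relat(graph: EmbeddingGraph) -> list[tuple[str, str]]:
    """REL(X, RP) ∧ RCMOD(ANT, X) ⇒ COREF(RP, ANT)."""
    rel_arcs = [(src, tgt) for t, src, tgt in graph.arcs() if t == "REL"]
    rcmod_arcs = [(src, tgt) for t, src, tgt in graph.arcs() if t == "RCMOD"]
    out = []
    for x, rp in rel_arcs:
        if graph.element(rp).lemma.lower() not in RELATIVE_PRONOUNS:
            continue
        for ant, x2 in rcmod_arcs:
            if x2 == x:
                out.append((rp, ant))
    return out


def resolve_appos(graph: EmbeddingGraph) -> list[tuple[str, str]]:
    """Appositive-family arcs yield COREF, anaphor normalised to the later
    mention in document order."""
    out = []
    for t, src, tgt in graph.arcs():
        if t in APPOS_RELATIONS:
            a, b = graph.element(src), graph.element(tgt)
            if (a.sentence_index, a.char_span) <= (b.sentence_index, b.char_span):
                out.append((tgt, src))
            else:
                out.append((src, tgt))
    return out


# -----------------------------------------------------------------------------
# PRON and DNP


def candidate_antecedents(anaphor: AnaphorMention, graph: EmbeddingGraph,
                          lexicons: CompatibilityLexicons,
                          paragraph_of: Optional[dict[int, int]] = None
                          ) -> list[SurfaceElement]:
    """Prior nodes in the paragraph window that are bound, hypernym-headed or
    conjunctions, ordered by increasing embedding-graph distance."""
    a = anaphor.node
    para = paragraph_of or {}
    window_para = para.get(a.sentence_index, 0)
    candidates = []
    for el in graph.elements():
        if el.id == a.id:
            continue
        if (el.sentence_index, el.char_span) >= (a.sentence_index, a.char_span):
            continue
        if para.get(el.sentence_index, 0) != window_para:
            continue
        if not (el.is_bound or head_lemma(el) in lexicons.hypernyms
                or is_conjunction(graph, el.id)):
            continue
        candidates.append(el)

    def sort_key(el: SurfaceElement):
        dist = graph.undirected_distance(a.id, el.id)
        dist = dist if dist is not None else 10 ** 6
        tok_dist = abs(a.char_span[0] - el.char_span[0])
        return (dist, tok_dist, el.sentence_index, el.char_span)

    return sorted(candidates, key=sort_key)


def _same_event_lexicalization(anaphor_entry: TriggerEntry,
                               candidate_entry: TriggerEntry) -> bool:
    """Event constraint: same lexicon semantic type and same lemma stem."""
    if anaphor_entry.semantic_type != candidate_entry.semantic_type:
        return False
    return _stem(anaphor_entry.lemma) == _stem(candidate_entry.lemma)


def _stem(lemma: str) -> str:
    for suffix in ("ations", "ation", "ated", "ates", "ate", "ions", "ion",
                   "ing", "ed", "es", "s", "e"):
        if lemma.endswith(suffix) and len(lemma) - len(suffix) >= 4:
            return lemma[: -len(suffix)]
    return lemma


def compatible(anaphor: AnaphorMention, candidate: SurfaceElement,
               graph: EmbeddingGraph, lexicons: CompatibilityLexicons) -> bool:
    """Agreement (and, for DNP, at least one semantic constraint)."""
    cand_number = number_of(graph, candidate)
    if anaphor.klass == PRON:
        # third person only; verbal triggers have undefined number and never agree
        return cand_number is not None and cand_number == anaphor.number

    if anaphor.klass != DNP:
        raise ValueError("compatible() applies to PRON and DNP anaphora")
    if anaphor.number is not None and cand_number is not None \
            and anaphor.number != cand_number:
        return False

    head = anaphor.head_lemma
    conj = is_conjunction(graph, candidate.id)

    # head word constraint: "the gene" <- "CD4 gene"
    if head and head == head_lemma(candidate):
        return True
    # singular hypernymy: "this protein" <- any entity mention
    if anaphor.number != "plural" and head in lexicons.hypernyms and candidate.is_entity:
        return True
    # plural hypernymy (set-instance anaphora): "these factors" <- "CD1, CD2 and CD3"
    if anaphor.number == "plural" and head in lexicons.hypernyms and conj:
        return True
    # meronymy: "the dimer" <- a conjunction of entities
    if head in lexicons.meronyms and conj:
        return True
    # event constraint: "the phosphorylation" <- "phosphorylated"
    a_entry = anaphor.node.bound_object
    c_entry = candidate.bound_object
    if isinstance(a_entry, TriggerEntry) and isinstance(c_entry, TriggerEntry):
        if _same_event_lexicalization(a_entry, c_entry):
            return True
    return False


def blocked(anaphor: AnaphorMention, candidate: SurfaceElement,
            graph: EmbeddingGraph) -> bool:
    """Structural blockers over the embedding graph."""
    a_id, c_id = anaphor.node.id, candidate.id
    # 1. direct embedding either way
    for t, tgt in graph.out_arcs(a_id):
        if tgt == c_id:
            return True
    for t, src in graph.in_arcs(a_id):
        if src == c_id:
            return True
    # shared governor configurations
    for t_a, gov in graph.in_arcs(a_id):
        for t_c, gov_c in graph.in_arcs(c_id):
            if gov != gov_c:
                continue
            # 2. candidate subject / anaphor object, unless reflexive
            if t_c in SUBJECT_ARCS and t_a in OBJECT_ARCS and not anaphor.reflexive:
                return True
            # 3. anaphor adjunct / candidate subject
            if t_c in SUBJECT_ARCS and t_a.startswith("PREP"):
                return True
    return False


def resolve_pron_dnp(graph: EmbeddingGraph, lexicons: CompatibilityLexicons,
                     classes: frozenset[str] = frozenset({PRON, DNP}),
                     paragraph_of: Optional[dict[int, int]] = None
                     ) -> list[tuple[str, str]]:
    """Closest unblocked compatible candidate per anaphor; a plural anaphor
    over a conjunction yields one COREF arc per conjunct."""
    arcs: list[tuple[str, str]] = []
    for anaphor in detect_anaphors(graph, classes):
        for cand in candidate_antecedents(anaphor, graph, lexicons, paragraph_of):
            if not compatible(anaphor, cand, graph, lexicons):
                continue
            if blocked(anaphor, cand, graph):
                continue
            if anaphor.number == "plural" and is_conjunction(graph, cand.id):
                for t, tgt in graph.out_arcs(cand.id):
                    if t == "CC":
                        arcs.append((anaphor.node.id, tgt))
            else:
                arcs.append((anaphor.node.id, cand.id))
            break
    return arcs


def resolve_all(graph: EmbeddingGraph,
                lexicons: Optional[CompatibilityLexicons] = None,
                classes: Iterable[str] = ALL_CLASSES,
                paragraph_of: Optional[dict[int, int]] = None) -> int:
    """Run the enabled coreference classes and add COREF arcs in place.

    Returns the number of arcs added.  COREF arcs always point from the
    anaphor to a node earlier in (or level with) document order and never
    connect a structurally blocked pair.
    """
    lexicons = lexicons or CompatibilityLexicons()
    classes = frozenset(classes)
    arcs: list[tuple[str, str]] = []
    if RELAT in classes:
        arcs += resolve_relat(graph)
    if APPOS in classes:
        arcs += resolve_appos(graph)
    pron_dnp = classes & {PRON, DNP}
    if pron_dnp:
        arcs += resolve_pron_dnp(graph, lexicons, frozenset(pron_dnp), paragraph_of)
    added = 0
    for ana, ant in arcs:
        if graph.add_relation("COREF", ana, ant):
            added += 1
    return added
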