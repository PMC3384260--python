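"""Core domain model: surface elements, predications and the scope calculus.

The central object is the :class:`Predication` — a predicate together with a
scalar modality value (mv), a polarity and an ordered argument list.  A
predication is *atomic* when all of its arguments are ontologically simple
(entities or free surface elements) and *embedding* when at least one argument
is itself a predication (causation, speculation, negation over an event).

Embedding semantic types are organised in four classes — MODAL, ATTRIBUTIVE,
RELATIONAL and VALENCE_SHIFTER — mirroring the linguistic typology the
composition calculus is built on.  Atomic semantic types are domain event
types (GENE_EXPRESSION, BINDING, ...) and are whatever the trigger lexicon
declares; anything not in the embedding taxonomy is treated as atomic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"
POLARITIES = (POSITIVE, NEGATIVE, NEUTRAL)

# --- embedding type taxonomy -------------------------------------------------

MODAL_TYPES = {
    "EPISTEMIC", "ASSUMPTIVE", "SPECULATIVE",
    "EVIDENTIAL", "DEDUCTIVE", "DEMONSTRATIVE", "REPORTING",
    "DYNAMIC", "POTENTIAL", "VOLITIVE",
    "DEONTIC", "OBLIGATIVE", "PERMISSIVE",
    "INTENTIONAL", "INTERROGATIVE", "SUCCESS",
}
RELATIONAL_TYPES = {"CAUSAL", "TEMPORAL", "CORRELATIVE", "COMPARATIVE", "SALIENCY"}
ATTRIBUTIVE_TYPES = {"PATIENT", "AGENTIVE", "EXPERIENCER"}
VALENCE_SHIFTER_TYPES = {"NEGATOR", "INTENSIFIER", "DIMINISHER"}

EMBEDDING_TYPES = (
    MODAL_TYPES | RELATIONAL_TYPES | ATTRIBUTIVE_TYPES | VALENCE_SHIFTER_TYPES
)


def category_of(semantic_type: str) -> Optional[str]:
    """Return the embedding class of a semantic type, or None for atomic types."""
    if semantic_type in MODAL_TYPES:
        return "MODAL"
    if semantic_type in RELATIONAL_TYPES:
        return "RELATIONAL"
    if semantic_type in ATTRIBUTIVE_TYPES:
        return "ATTRIBUTIVE"
    if semantic_type in VALENCE_SHIFTER_TYPES:
        return "VALENCE_SHIFTER"
    return None


def is_operator_type(semantic_type: str) -> bool:
    """MODAL and VALENCE_SHIFTER predicates rescale modality values."""
    return category_of(semantic_type) in ("MODAL", "VALENCE_SHIFTER")


# --- surface layer -----------------------------------------------------------

ENTITY = "entity"
PREDICATE = "predicate"
FREE = "free"


@dataclass
class EntityMention:
    """A text-bound, ontologically simple entity (a standoff T annotation)."""

    id: str
    semantic_type: str
    char_span: tuple[int, int]  # 0-based, half-open
    text: str

    def __hash__(self) -> int:
        return hash(("entity", self.id))


@dataclass
class SurfaceElement:
    """A token or collapsed contiguous multi-token unit.

    A surface element is *semantically bound* when it is associated with an
    entity or a trigger (``binding != "free"``); free elements behave as
    entities of unknown semantic type.
    """

    id: str
    tokens: tuple[int, ...]          # 1-based token indices within sentence
    char_span: tuple[int, int]
    sentence_index: int
    text: str
    lemma: str = ""
    pos: str = ""
    binding: str = FREE              # entity | predicate | free
    bound_object: object = None      # EntityMention or TriggerEntry
    virtual: bool = False            # synthesised node (e.g. implicit conjunction)

    def __post_init__(self) -> None:
        if self.binding not in (ENTITY, PREDICATE, FREE):
            raise ValueError(f"invalid binding {self.binding!r}")
        if not self.virtual and len(self.tokens) < 1:
            raise ValueError("surface element must cover at least one token")

    @property
    def is_bound(self) -> bool:
        return self.binding != FREE

    @property
    def is_entity(self) -> bool:
        return self.binding == ENTITY

    @property
    def is_predicate(self) -> bool:
        return self.binding == PREDICATE

    def __hash__(self) -> int:
        return hash(("element", self.id))


@dataclass(frozen=True)
class EmbeddingRelation:
    """A typed, directed semantic arc between two surface elements.

    Types are uppercase by convention, distinguishing them from the syntactic
    dependency labels they are derived from.
    """

    type: str
    source: str
    target: str

    def __post_init__(self) -> None:
        if self.type != self.type.upper():
            raise ValueError(f"embedding relation type must be uppercase: {self.type!r}")
        if self.source == self.target:
            raise ValueError("self-loop embedding relation")


# --- predications ------------------------------------------------------------

OBJECT = "Object"
SUBJECT = "Subject"
ADJUNCT = "Adjunct"
ARG_TYPES = (OBJECT, SUBJECT, ADJUNCT)

ArgValue = Union[EntityMention, SurfaceElement, "Predication"]


@dataclass
class Argument:
    arg_type: str
    value: ArgValue

    def __post_init__(self) -> None:
        if self.arg_type not in ARG_TYPES:
            raise ValueError(f"unknown argument type {self.arg_type!r}")


@dataclass
class Predication:
    """Predicate + scalar modality value + polarity + ordered arguments.

    ``args`` is kept in canonical order: Object first, Subject second, then
    adjuncts.  ``mv`` lives in [0, 1]: 1 is the strongest association with the
    governing modal scale, 0 is negative association.
    """

    id: str
    predicate: SurfaceElement
    semantic_type: str
    mv: float = 1.0
    polarity: str = NEUTRAL
    args: list[Argument] = field(default_factory=list)
    negated: bool = False            # set when a NEGATOR inverted this predication

    def __post_init__(self) -> None:
        self._check_mv()
        if self.polarity not in POLARITIES:
            raise ValueError(f"invalid polarity {self.polarity!r}")

    def _check_mv(self) -> None:
        if not (0.0 <= self.mv <= 1.0):
            raise ValueError(f"mv out of range: {self.mv}")

    @property
    def object(self) -> Optional[ArgValue]:
        for a in self.args:
            if a.arg_type == OBJECT:
                return a.value
        return None

    @property
    def subject(self) -> Optional[ArgValue]:
        for a in self.args:
            if a.arg_type == SUBJECT:
                return a.value
        return None

    @property
    def adjuncts(self) -> list[ArgValue]:
        return [a.value for a in self.args if a.arg_type == ADJUNCT]

    @property
    def predication_args(self) -> list["Predication"]:
        return [a.value for a in self.args if isinstance(a.value, Predication)]

    @property
    def is_atomic(self) -> bool:
        """Atomic: all arguments are ontologically simple (no predication args)."""
        return not self.predication_args

    @property
    def is_embedding(self) -> bool:
        return not self.is_atomic

    @property
    def category(self) -> Optional[str]:
        return category_of(self.semantic_type)

    def __hash__(self) -> int:
        return hash(("predication", self.id))

    def __repr__(self) -> str:  # compact, mirrors the m:SEM(id, args) notation
        argrepr = ",".join(
            a.value.id if hasattr(a.value, "id") else repr(a.value) for a in self.args
        )
        return (
            f"{self.predicate.lemma or self.predicate.text}:"
            f"{self.semantic_type}({self.id},{self.mv:g},{self.polarity},{argrepr})"
        )


class CycleError(RuntimeError):
    """The predication graph contains a cycle — a composition bug."""


def embeds(pr1: Predication, pr2: Predication) -> bool:
    """True iff ``pr2`` is a (direct) argument of ``pr1``."""
    return any(isinstance(a.value, Predication) and a.value.id == pr2.id
               for a in pr1.args)


def scope(pr: Predication, _seen: Optional[frozenset] = None) -> set[Predication]:
    """All predications within the scope of ``pr`` (transitive closure of embeds).

    The scope relation is a strict partial order: transitive and irreflexive.
    Raises :class:`CycleError` if the embedding structure is cyclic.
    """
    seen = _seen or frozenset()
    if pr.id in seen:
        raise CycleError(f"cycle through predication {pr.id}")
    out: set[Predication] = set()
    for child in pr.predication_args:
        out.add(child)
        out |= scope(child, seen | {pr.id})
    return out


def sort_args(args: Iterable[Argument]) -> list[Argument]:
    """Canonical order: Object, Subject, then adjuncts (stable within class)."""
    rank = {OBJECT: 0, SUBJECT: 1, ADJUNCT: 2}
    return sorted(args, key=lambda a: rank[a.arg_type])
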