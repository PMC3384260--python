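"""Mapping composed predications to shared-task event annotations.

Three steps: (1) type mapping — embedding predication types become event or
modification types under constraints on type, polarity and modality value;
(2) role mapping — logical arguments (Object/Subject/Adjunct) become semantic
roles (Theme/Cause/Participant/Scope); (3) pruning — participants that do not
conform to the event definition or are semantically free are dropped, as are
predications whose types could not be mapped, with the removal cascading
through events that referenced them.  The ID-track PROCESS type is the one
event allowed to keep zero participants.

Speculation and Negation are emitted as modification annotations targeting
the innermost mapped events within the modal's scope; an event whose
predication was inverted by a negator also receives a Negation mark.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import EMBEDDING_TYPES, Predication, SurfaceElement

TRACKS = ("GENIA", "EPI", "ID")
MODIFICATION_TYPES = {"SPECULATION", "NEGATION"}
ROLES = ("Theme", "Cause", "Participant", "Scope")


@dataclass(frozen=True)
class TypeMappingRule:
    tracks: frozenset[str]
    predication_type: str
    polarity_constraint: str = "any"        # positive | negative | neutral | any
    mv_constraint: str = "-"                # e.g. ">0.0", "<=0.5", "-"
    output: str = ""

    def matches(self, pred: Predication, track: str) -> bool:
        if track not in self.tracks:
            return False
        if pred.semantic_type != self.predication_type:
            return False
        if self.polarity_constraint not in ("any", "-") \
                and pred.polarity != self.polarity_constraint:
            return False
        return _mv_ok(self.mv_constraint, pred.mv)


def _mv_ok(constraint: str, mv: float) -> bool:
    if constraint in ("-", "", "any"):
        return True
    m = re.fullmatch(r"(>=|<=|>|<|==|=)\s*([0-9.]+)", constraint)
    if not m:
        raise ValueError(f"bad mv constraint {constraint!r}")
    op, val = m.group(1), float(m.group(2))
    return {">": mv > val, ">=": mv >= val, "<": mv < val,
            "<=": mv <= val, "=": mv == val, "==": mv == val}[op]


@dataclass(frozen=True)
class RoleMappingRule:
    logical_arg: str                        # Object | Subject | Adjunct
    constrained_to: frozenset[str] = frozenset()
    exclusions: frozenset[str] = frozenset()
    role: str = "Theme"

    def __post_init__(self):
        if self.constrained_to & self.exclusions:
            raise ValueError("constrained_to and exclusions overlap")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    def matches(self, logical_arg: str, event_type: str) -> bool:
        if logical_arg != self.logical_arg:
            return False
        if self.constrained_to and event_type not in self.constrained_to:
            return False
        if event_type in self.exclusions:
            return False
        return True


@dataclass(frozen=True)
class EventDefinition:
    track: str
    event_type: str
    allowed_roles: frozenset[str]
    mandatory_roles: frozenset[str]


@dataclass
class EventAnnotation:
    id: str                                 # E-number
    event_type: str                         # internal uppercase label
    trigger: SurfaceElement
    participants: list[tuple[str, object]] = field(default_factory=list)
    predication: Optional[Predication] = None


@dataclass
class ModificationAnnotation:
    id: str                                 # M-number
    mod_type: str                           # NEGATION | SPECULATION
    target: EventAnnotation
    trigger: Optional[SurfaceElement] = None


# -----------------------------------------------------------------------------
# rule/definition file loading (TSV mirrors of the mapping tables)


def _tsv_rows(source) -> list[list[str]]:
    if isinstance(source, (str, os.PathLike)):
        with open(source, encoding="utf-8") as fh:
            return _tsv_rows(list(fh))
    rows = []
    for raw in source:
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append([c.strip() for c in line.split("\t")])
    return rows


def _parse_set(col: str, upper: bool = True) -> frozenset[str]:
    if col in ("-", ""):
        return frozenset()
    items = [c.strip() for c in col.split(",")]
    return frozenset(c.upper() if upper else c for c in items)


def load_type_rules(source) -> list[TypeMappingRule]:
    rules = []
    for cols in _tsv_rows(source):
        if len(cols) != 5:
            raise ValueError(f"type mapping row needs 5 columns: {cols}")
        rules.append(TypeMappingRule(
            tracks=_parse_set(cols[0]),
            predication_type=cols[1].upper(),
            polarity_constraint=cols[2].lower() if cols[2] not in ("-", "") else "any",
            mv_constraint=cols[3],
            output=cols[4].upper(),
        ))
    return rules


def load_role_rules(source) -> list[RoleMappingRule]:
    rules = []
    for cols in _tsv_rows(source):
        if len(cols) != 4:
            raise ValueError(f"role mapping row needs 4 columns: {cols}")
        rules.append(RoleMappingRule(
            logical_arg=cols[0],
            constrained_to=_parse_set(cols[1]),
            exclusions=_parse_set(cols[2]),
            role=cols[3],
        ))
    return rules


def load_event_definitions(source) -> list[EventDefinition]:
    defs = []
    for cols in _tsv_rows(source):
        if len(cols) != 4:
            raise ValueError(f"event definition row needs 4 columns: {cols}")
        defs.append(EventDefinition(
            track=cols[0].upper(),
            event_type=cols[1].upper(),
            allowed_roles=_parse_set(cols[2], upper=False),
            mandatory_roles=_parse_set(cols[3], upper=False),
        ))
    return defs


# -----------------------------------------------------------------------------
# the three mapping steps


def map_types(predications: Iterable[Predication], rules: list[TypeMappingRule],
              track: str) -> dict[str, Optional[str]]:
    """Per predication: the mapped event/modification type, or None.

    Embedding-category predications go through the rule table (first match
    wins); atomic predications keep their own event type.
    """
    out: dict[str, Optional[str]] = {}
    for pred in predications:
        if pred.semantic_type in EMBEDDING_TYPES:
            mapped = None
            for rule in rules:
                if rule.matches(pred, track):
                    mapped = rule.output
                    break
            out[pred.id] = mapped
        else:
            out[pred.id] = pred.semantic_type
    return out


def map_roles(pred: Predication, event_type: str,
              rules: list[RoleMappingRule]) -> list[tuple[str, object]]:
    """Convert logical arguments to semantic roles (first matching rule wins);
    arguments matched by no rule are carried forward unmapped as (None, v)."""
    out = []
    for arg in pred.args:
        role = None
        for rule in rules:
            if rule.matches(arg.arg_type, event_type):
                role = rule.role
                break
        out.append((role, arg.value))
    return out


@dataclass
class MappingResult:
    events: list[EventAnnotation]
    modifications: list[ModificationAnnotation]
    unmapped: list[Predication]


def map_document(predications: list[Predication], track: str,
                 type_rules: list[TypeMappingRule],
                 role_rules: list[RoleMappingRule],
                 event_defs: list[EventDefinition]) -> MappingResult:
    """Full mapping phase: types, roles, pruning, modification fan-out."""
    track = track.upper()
    defs = {d.event_type: d for d in event_defs if d.track == track}
    typed = map_types(predications, type_rules, track)
    by_id = {p.id: p for p in predications}

    candidates: dict[str, EventAnnotation] = {}
    mod_preds: list[tuple[Predication, str]] = []
    unmapped: list[Predication] = []
    for pred in predications:
        mapped = typed[pred.id]
        if mapped is None:
            unmapped.append(pred)
        elif mapped in MODIFICATION_TYPES:
            mod_preds.append((pred, mapped))
        elif mapped in defs:
            roles = map_roles(pred, mapped, role_rules)
            candidates[pred.id] = EventAnnotation(
                id="", event_type=mapped, trigger=pred.predicate,
                participants=roles, predication=pred)
        else:
            unmapped.append(pred)           # event type undefined for this track

    # pruning with cascade
    changed = True
    while changed:
        changed = False
        for pid, ev in list(candidates.items()):
            definition = defs[ev.event_type]
            kept = []
            for role, value in ev.participants:
                if role is None or role not in definition.allowed_roles:
                    continue                # non-conforming participant
                if isinstance(value, SurfaceElement):
                    continue                # semantically free participant
                if isinstance(value, Predication) and value.id not in candidates:
                    continue                # referenced sub-event was dropped
                kept.append((role, value))
            if kept != ev.participants:
                ev.participants = kept
                changed = True
            mandatory = definition.mandatory_roles
            if mandatory and not any(r in mandatory for r, _ in ev.participants):
                del candidates[pid]         # PROCESS has no mandatory roles
                unmapped.append(ev.predication)
                changed = True

    # deterministic event ids, in document order of the trigger
    events = sorted(
        candidates.values(),
        key=lambda e: (e.trigger.sentence_index, e.trigger.char_span, e.predication.id))
    for i, ev in enumerate(events, 1):
        ev.id = f"E{i}"
    ev_by_pred = {ev.predication.id: ev for ev in events}
    for ev in events:
        ev.participants = [
            (role, ev_by_pred[v.id] if isinstance(v, Predication) else v)
            for role, v in ev.participants
        ]

    # modifications: innermost mapped events within the operator's scope
    def frontier(pred: Predication) -> list[EventAnnotation]:
        out, queue, seen = [], list(pred.predication_args), set()
        while queue:
            p = queue.pop(0)
            if p.id in seen:
                continue
            seen.add(p.id)
            if p.id in ev_by_pred:
                out.append(ev_by_pred[p.id])
            else:
                queue.extend(p.predication_args)
        return out

    mods: list[ModificationAnnotation] = []
    recorded: set[tuple[str, str]] = set()
    for pred, mod_type in mod_preds:
        for ev in frontier(pred):
            if (mod_type, ev.id) not in recorded:
                recorded.add((mod_type, ev.id))
                mods.append(ModificationAnnotation(
                    id="", mod_type=mod_type, target=ev, trigger=pred.predicate))
    for ev in events:                       # negator-inverted events
        if ev.predication.negated and ("NEGATION", ev.id) not in recorded:
            recorded.add(("NEGATION", ev.id))
            mods.append(ModificationAnnotation(id="", mod_type="NEGATION", target=ev))
    mods.sort(key=lambda m: (m.mod_type != "NEGATION", int(m.target.id[1:])))
    for i, m in enumerate(mods, 1):
        m.id = f"M{i}"
    return MappingResult(events=events, modifications=mods, unmapped=unmapped)
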