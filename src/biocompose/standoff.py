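"""BioNLP standoff I/O and the end-to-end pipeline.

Reads document text (.txt), gold entities (.a1, T lines, 0-based half-open
offsets) and per-sentence dependency parses (.dep); writes event (.a2)
annotations.  Two dependency dialects are auto-detected:

* CoNLL-style rows — ``index form lemma POS head label`` with an optional
  seventh column of extra ``head:label`` pairs (conjunct propagation gives a
  token several governors, which single-head CoNLL cannot express);
* relation lines — ``label(governor-3, dependent-5)``; token forms are
  recovered from the mention strings (lemma defaults to the lowercased form,
  POS is unknown and acts as a wildcard downstream).

Sentences are blank-line-separated blocks in both dialects.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from importlib import resources

from .compose import (
    ArgumentRule, CompositionConfig, compose_document, load_argument_rules,
)
from .coref import ALL_CLASSES, CompatibilityLexicons, resolve_all
from .graph import ParsedSentence, SyntacticDependency, Token, build_document_graph
from .lexicon import Lexicon, load_lexicon
from .mapping import (
    EventAnnotation, MappingResult, ModificationAnnotation,
    load_event_definitions, load_role_rules, load_type_rules, map_document,
)
from .model import EntityMention

log = logging.getLogger(__name__)


class StandoffError(ValueError):
    pass


@dataclass
class StandoffDocument:
    doc_id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    sentences: list[ParsedSentence] = field(default_factory=list)

    @property
    def max_t_index(self) -> int:
        best = 0
        for e in self.entities:
            m = re.fullmatch(r"T(\d+)", e.id)
            if m:
                best = max(best, int(m.group(1)))
        return best

    def paragraph_of(self) -> dict[int, int]:
        return {s.index: s.paragraph for s in self.sentences}


# -----------------------------------------------------------------------------
# reading


def read_txt_a1(txt_path: Union[str, Path], a1_path: Union[str, Path]) -> StandoffDocument:
    """Read document text and gold entity annotations, validating offsets."""
    txt_path, a1_path = Path(txt_path), Path(a1_path)
    text = txt_path.read_text(encoding="utf-8")
    entities: list[EntityMention] = []
    for lineno, line in enumerate(a1_path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            raise StandoffError(f"{a1_path}:{lineno}: expected a T line, got {line!r}")
        try:
            tid, middle, mention = line.split("\t")
            etype, start, end = middle.rsplit(" ", 2)
            start, end = int(start), int(end)
        except ValueError as exc:
            raise StandoffError(f"{a1_path}:{lineno}: malformed T line") from exc
        if text[start:end] != mention:
            raise StandoffError(
                f"{a1_path}:{lineno}: span text mismatch: "
                f"{text[start:end]!r} != {mention!r}")
        entities.append(EntityMention(id=tid, semantic_type=etype,
                                      char_span=(start, end), text=mention))
    return StandoffDocument(doc_id=txt_path.stem, text=text, entities=entities)


_REL_LINE = re.compile(r"([A-Za-z_0-9']+)\((.+)-(\d+)('?),\s*(.+)-(\d+)('?)\)")


def read_dependencies(source: Union[str, Path, Iterable[str]]) -> list[ParsedSentence]:
    """Parse a dependency file in either dialect into per-sentence lists."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    else:
        lines = [l.rstrip("\n") for l in source]

    blocks: list[list[tuple[int, str]]] = [[]]
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            if blocks[-1]:
                blocks.append([])
        elif not line.lstrip().startswith("#"):
            blocks[-1].append((lineno, line))
    if blocks and not blocks[-1]:
        blocks.pop()

    sentences = []
    for i, block in enumerate(blocks):
        first = block[0][1]
        if _REL_LINE.fullmatch(first.strip()):
            sentences.append(_parse_relation_block(block, i))
        else:
            sentences.append(_parse_conll_block(block, i))
    return sentences


def _parse_relation_block(block, index: int) -> ParsedSentence:
    forms: dict[int, str] = {}
    deps = []
    for lineno, line in block:
        m = _REL_LINE.fullmatch(line.strip())
        if not m:
            raise StandoffError(f"line {lineno}: malformed relation line {line!r}")
        label, gform, gidx, _, dform, didx, _ = m.groups()
        gidx, didx = int(gidx), int(didx)
        forms.setdefault(gidx, gform)
        forms.setdefault(didx, dform)
        deps.append(SyntacticDependency(label=label, governor=gidx, dependent=didx))
    tokens = [Token(index=i, form=forms[i]) for i in sorted(forms)]
    return ParsedSentence(tokens=tokens, deps=deps, index=index)


def _parse_conll_block(block, index: int) -> ParsedSentence:
    tokens, deps = [], []
    for lineno, line in block:
        cols = re.split(r"\t| {2,}", line.strip())
        if len(cols) == 1:
            cols = line.split()
        if len(cols) < 6:
            raise StandoffError(f"line {lineno}: expected >=6 CoNLL columns, got {line!r}")
        try:
            idx = int(cols[0])
            head = int(cols[4])
        except ValueError as exc:
            raise StandoffError(f"line {lineno}: bad index/head in {line!r}") from exc
        tokens.append(Token(index=idx, form=cols[1], lemma=cols[2], pos=cols[3]))
        if head != 0:
            deps.append(SyntacticDependency(label=cols[5], governor=head, dependent=idx))
        if len(cols) >= 7 and cols[6] not in ("-", "_", ""):
            for extra in cols[6].split("|"):
                h, lab = extra.split(":", 1)
                deps.append(SyntacticDependency(label=lab, governor=int(h), dependent=idx))
    return ParsedSentence(tokens=tokens, deps=deps, index=index)


def align_tokens(text: str, sentences: list[ParsedSentence]) -> list[ParsedSentence]:
    """Assign character spans to tokens by scanning the document text in order,
    and paragraph indices from blank-line boundaries."""
    cursor = 0
    para_breaks = [m.start() for m in re.finditer(r"\n\s*\n", text)]
    out = []
    for sent in sentences:
        new_tokens = []
        for tok in sent.tokens:
            pos = text.find(tok.form, cursor)
            if pos < 0:
                pos = text.lower().find(tok.form.lower(), cursor)
            if pos < 0:
                raise StandoffError(
                    f"cannot align token {tok.form!r} (sentence {sent.index})")
            span = (pos, pos + len(tok.form))
            cursor = span[1]
            new_tokens.append(Token(index=tok.index, form=tok.form,
                                    lemma=tok.lemma, pos=tok.pos, char_span=span))
        start = new_tokens[0].char_span[0] if new_tokens else 0
        paragraph = sum(1 for b in para_breaks if b < start)
        out.append(ParsedSentence(tokens=new_tokens, deps=sent.deps,
                                  index=sent.index, paragraph=paragraph))
    return out


# -----------------------------------------------------------------------------
# writing


def task_label(internal: str) -> str:
    """GENE_EXPRESSION -> Gene_expression (shared-task capitalisation)."""
    return internal[0].upper() + internal[1:].lower()


def write_a2(events: list[EventAnnotation],
             modifications: list[ModificationAnnotation],
             max_t_index: int = 0) -> str:
    """Serialise events and modifications; trigger T lines are numbered after
    the .a1 maximum.  Refuses to write dangling references."""
    event_ids = {ev.id for ev in events}
    for ev in events:
        for role, val in ev.participants:
            if isinstance(val, EventAnnotation) and val.id not in event_ids:
                raise StandoffError(f"dangling event reference {val.id} in {ev.id}")
    for m in modifications:
        if m.target.id not in event_ids:
            raise StandoffError(f"dangling modification target {m.target.id}")

    lines = []
    trigger_ids: dict[tuple, str] = {}
    next_t = max_t_index + 1
    for ev in events:
        key = (ev.trigger.char_span, ev.event_type)
        if key not in trigger_ids:
            trigger_ids[key] = f"T{next_t}"
            next_t += 1
            lines.append(
                f"{trigger_ids[key]}\t{task_label(ev.event_type)} "
                f"{ev.trigger.char_span[0]} {ev.trigger.char_span[1]}\t{ev.trigger.text}")
    for ev in events:
        tid = trigger_ids[(ev.trigger.char_span, ev.event_type)]
        parts = []
        role_count: dict[str, int] = {}
        for role, val in ev.participants:
            n = role_count.get(role, 0) + 1
            role_count[role] = n
            label = role if n == 1 else f"{role}{n}"
            ref = val.id if isinstance(val, (EventAnnotation, EntityMention)) else str(val)
            parts.append(f"{label}:{ref}")
        body = f"{task_label(ev.event_type)}:{tid}"
        lines.append(f"{ev.id}\t{body}" + (" " + " ".join(parts) if parts else ""))
    for m in modifications:
        lines.append(f"{m.id}\t{task_label(m.mod_type)} {m.target.id}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_a2(content: str):
    """Parse .a2 content back into plain tuples (for round-trip checks)."""
    triggers, events, mods = {}, [], []
    for line in content.splitlines():
        if not line.strip():
            continue
        tid, rest = line.split("\t", 1)
        if tid.startswith("T"):
            middle, text = rest.split("\t")
            etype, start, end = middle.rsplit(" ", 2)
            triggers[tid] = (etype, int(start), int(end), text)
        elif tid.startswith("E"):
            fields = rest.split(" ")
            etype, trig = fields[0].split(":")
            parts = [tuple(f.split(":", 1)) for f in fields[1:] if f]
            events.append((tid, etype, trig, parts))
        elif tid.startswith("M"):
            mod_type, target = rest.split(" ")
            mods.append((tid, mod_type, target))
    return triggers, events, mods


# -----------------------------------------------------------------------------
# resources and pipeline


def _data_path(name: str):
    return resources.files("biocompose").joinpath("data").joinpath(name)


def default_lexicon() -> Lexicon:
    return load_lexicon(_data_path("lexicon.tsv").read_text().splitlines())


def default_argument_rules() -> list[ArgumentRule]:
    return load_argument_rules(_data_path("arg_rules.tsv").read_text().splitlines())


def default_type_rules():
    return load_type_rules(_data_path("type_map.tsv").read_text().splitlines())


def default_role_rules():
    return load_role_rules(_data_path("role_map.tsv").read_text().splitlines())


def default_event_definitions():
    return load_event_definitions(_data_path("event_defs.tsv").read_text().splitlines())


@dataclass
class PipelineConfig:
    track: str = "GENIA"
    lexicon: Optional[Lexicon] = None
    arg_rules: Optional[list[ArgumentRule]] = None
    type_rules: Optional[list] = None
    role_rules: Optional[list] = None
    event_defs: Optional[list] = None
    coref_classes: frozenset[str] = ALL_CLASSES
    compat: Optional[CompatibilityLexicons] = None
    propagation_depth: Optional[int] = None

    def resolved(self) -> "PipelineConfig":
        return PipelineConfig(
            track=self.track.upper(),
            lexicon=self.lexicon if self.lexicon is not None else default_lexicon(),
            arg_rules=self.arg_rules if self.arg_rules is not None else default_argument_rules(),
            type_rules=self.type_rules if self.type_rules is not None else default_type_rules(),
            role_rules=self.role_rules if self.role_rules is not None else default_role_rules(),
            event_defs=self.event_defs if self.event_defs is not None else default_event_definitions(),
            coref_classes=frozenset(self.coref_classes),
            compat=self.compat or CompatibilityLexicons(),
            propagation_depth=self.propagation_depth,
        )


def process_document(doc: StandoffDocument,
                     config: Optional[PipelineConfig] = None) -> MappingResult:
    """Read -> graph -> coreference -> compose -> map, for one document."""
    cfg = (config or PipelineConfig()).resolved()
    sentences = align_tokens(doc.text, doc.sentences)
    graph = build_document_graph(sentences, doc.entities, cfg.lexicon)
    if cfg.coref_classes:
        n = resolve_all(graph, cfg.compat, cfg.coref_classes, doc.paragraph_of())
        log.debug("%s: %d COREF arcs", doc.doc_id, n)
    preds = compose_document(
        graph, cfg.arg_rules,
        CompositionConfig(propagation_depth=cfg.propagation_depth))
    log.debug("%s: %d predications", doc.doc_id, len(preds))
    return map_document(preds, cfg.track, cfg.type_rules, cfg.role_rules,
                        cfg.event_defs)


def run_pipeline(input_dir: Union[str, Path], out_dir: Union[str, Path],
                 config: Optional[PipelineConfig] = None) -> dict[str, MappingResult]:
    """Process every .txt/.a1/.dep triple in a directory, writing .a2 files."""
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = {}
    for txt in sorted(input_dir.glob("*.txt")):
        a1 = txt.with_suffix(".a1")
        dep = txt.with_suffix(".dep")
        if not a1.exists() or not dep.exists():
            raise StandoffError(f"missing .a1 or .dep for {txt.name}")
        doc = read_txt_a1(txt, a1)
        doc.sentences = read_dependencies(dep)
        result = process_document(doc, config)
        content = write_a2(result.events, result.modifications, doc.max_t_index)
        (out_dir / (txt.stem + ".a2")).write_text(content, encoding="utf-8")
        log.info("%s: %d events, %d modifications", doc.doc_id,
                 len(result.events), len(result.modifications))
        results[doc.doc_id] = result
    return results
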