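"""Trigger lexicon: six-feature predicate entries, matching, and MLE typing.

Each entry carries lemma, coarse POS, semantic type (an atomic event type or
an embedding category), polarity, category strength in [0, 1] and a
negative-raising flag.  One semantic type per (lemma, POS) pair — the lexicon
deliberately avoids sense disambiguation.

File format: tab-separated, six columns, ``#`` comments.  Blank trailing
columns default to polarity=neutral, strength=1.0, negative_raising=false.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, TextIO, Union

from .model import POLARITIES, NEUTRAL


@dataclass(frozen=True)
class TriggerEntry:
    lemma: str                 # lowercase; may contain spaces (multi-word)
    pos: str                   # coarse tag: VB, NN, JJ, RB, DT, MD, IN, ...
    semantic_type: str
    polarity: str = NEUTRAL
    category_strength: float = 1.0
    negative_raising: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.category_strength <= 1.0):
            raise ValueError(f"category strength out of [0,1]: {self.category_strength}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")


class LexiconError(ValueError):
    """Raised with the full list of offending rows on load failure."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid lexicon rows:\n" + "\n".join(problems))


# prefixes whose polarity overrides the base entry's when the stripped lemma
# is itself in the lexicon (nonexpression -> negative, upregulation -> positive)
AFFIX_POLARITY = {
    "non": "negative",
    "un": "negative",
    "in": "negative",
    "up": "positive",
    "down": "negative",
}


def coarse_pos(pos: str) -> str:
    """Map a Penn-style tag to the coarse category used by lexicon keys."""
    if not pos:
        return ""
    for prefix in ("VB", "NN", "JJ", "RB", "DT", "MD", "IN", "PRP", "CC", "TO", "WDT", "WP"):
        if pos.startswith(prefix):
            return prefix
    return pos


class Lexicon:
    """Indexed trigger dictionary keyed by (lemma, coarse POS)."""

    def __init__(self, entries: Iterable[TriggerEntry] = ()):
        self._by_key: dict[tuple[str, str], TriggerEntry] = {}
        self._by_lemma: dict[str, list[TriggerEntry]] = defaultdict(list)
        for e in entries:
            self.add(e)

    def add(self, entry: TriggerEntry) -> None:
        key = (entry.lemma, entry.pos)
        existing = self._by_key.get(key)
        if existing is not None and existing.semantic_type != entry.semantic_type:
            raise LexiconError(
                [f"duplicate ({entry.lemma!r},{entry.pos!r}) with conflicting types "
                 f"{existing.semantic_type} / {entry.semantic_type}"]
            )
        self._by_key[key] = entry
        if existing is None:
            self._by_lemma[entry.lemma].append(entry)

    def lookup(self, lemma: str, pos: str = "") -> Optional[TriggerEntry]:
        """Find an entry for a lemma; empty POS acts as a wildcard."""
        lemma = lemma.lower()
        if pos:
            hit = self._by_key.get((lemma, coarse_pos(pos)))
            if hit is not None:
                return hit
            return None
        candidates = self._by_lemma.get(lemma)
        return candidates[0] if candidates else None

    def lookup_with_affix(self, lemma: str, pos: str = "") -> Optional[TriggerEntry]:
        """Like lookup, but also tries polarity-bearing prefixes (non-, up-, ...)."""
        hit = self.lookup(lemma, pos)
        if hit is not None:
            return hit
        lem = lemma.lower().lstrip("-")
        for prefix, polarity in AFFIX_POLARITY.items():
            stripped = None
            if lem.startswith(prefix + "-"):
                stripped = lem[len(prefix) + 1:]
            elif lem.startswith(prefix):
                stripped = lem[len(prefix):]
            if stripped:
                base = self.lookup(stripped, pos)
                if base is not None:
                    return TriggerEntry(
                        lemma=lem, pos=base.pos, semantic_type=base.semantic_type,
                        polarity=polarity, category_strength=base.category_strength,
                        negative_raising=base.negative_raising,
                    )
        return None

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def entries(self) -> list[TriggerEntry]:
        return sorted(self._by_key.values(), key=lambda e: (e.lemma, e.pos))

    @property
    def multiword_lemmas(self) -> list[tuple[str, ...]]:
        return [tuple(e.lemma.split()) for e in self._by_key.values() if " " in e.lemma]


def _parse_bool(s: str) -> bool:
    s = s.strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def load_lexicon(source: Union[str, os.PathLike, TextIO, Iterable[str]]) -> Lexicon:
    """Load a six-column TSV lexicon; collects all row errors before raising."""
    if isinstance(source, (str, os.PathLike)):
        with open(source, encoding="utf-8") as fh:
            return load_lexicon(fh)
    lex = Lexicon()
    problems: list[str] = []
    for lineno, raw in enumerate(source, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            problems.append(f"line {lineno}: expected >=3 columns, got {len(cols)}")
            continue
        cols += [""] * (6 - len(cols))
        lemma, pos, sem, pol, strength, raising = (c.strip() for c in cols[:6])
        try:
            entry = TriggerEntry(
                lemma=lemma.lower(),
                pos=pos.upper(),
                semantic_type=sem.upper(),
                polarity=pol.lower() or NEUTRAL,
                category_strength=float(strength) if strength else 1.0,
                negative_raising=_parse_bool(raising),
            )
            lex.add(entry)
        except (ValueError, LexiconError) as exc:
            problems.append(f"line {lineno}: {exc}")
    if problems:
        raise LexiconError(problems)
    return lex


def save_lexicon(lex: Lexicon, path: Union[str, os.PathLike]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# lemma\tpos\tsemantic_type\tpolarity\tcategory_strength\tnegative_raising\n")
        for e in lex.entries():
            fh.write(
                f"{e.lemma}\t{e.pos}\t{e.semantic_type}\t{e.polarity}\t"
                f"{e.category_strength:g}\t{'true' if e.negative_raising else 'false'}\n"
            )


@dataclass(frozen=True)
class TriggerMention:
    """A lexicon match in a token sequence (1-based, inclusive token indices)."""

    token_indices: tuple[int, ...]
    lemma: str
    entry: TriggerEntry


def match_triggers(tokens, lexicon: Lexicon) -> list[TriggerMention]:
    """Match triggers greedily, longest-first, left to right; no overlaps.

    ``tokens`` is a sequence of objects with ``index``, ``lemma`` and ``pos``
    attributes.  Multi-word entries are matched on their lemma sequence alone;
    single-word entries additionally check coarse POS (empty POS = wildcard).
    """
    toks = list(tokens)
    max_len = max((len(t) for t in lexicon.multiword_lemmas), default=1)
    mentions: list[TriggerMention] = []
    i = 0
    while i < len(toks):
        matched = None
        for span in range(min(max_len, len(toks) - i), 0, -1):
            window = toks[i:i + span]
            lemma = " ".join(t.lemma.lower() for t in window)
            if span == 1:
                entry = lexicon.lookup_with_affix(lemma, window[0].pos)
            else:
                entry = lexicon.lookup(lemma)
                if entry is not None and " " not in entry.lemma:
                    entry = None
            if entry is not None:
                matched = TriggerMention(
                    token_indices=tuple(t.index for t in window),
                    lemma=lemma, entry=entry,
                )
                break
        if matched is not None:
            mentions.append(matched)
            i += len(matched.token_indices)
        else:
            i += 1
    return mentions


def assign_types_mle(counts: Iterable[tuple[str, str, str, int]]) -> dict[tuple[str, str], str]:
    """Assign each (lemma, pos) trigger the maximum-likelihood event type.

    ``counts`` rows are (lemma, pos, event_type, count).  Ties break to the
    lexicographically smallest type name; triggers with all-zero counts are
    excluded.  The result is invariant under row permutation.
    """
    table: dict[tuple[str, str], dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for lemma, pos, etype, count in counts:
        if count < 0:
            raise ValueError(f"negative count for ({lemma},{pos},{etype})")
        table[(lemma.lower(), pos.upper())][etype.upper()] += count
    out: dict[tuple[str, str], str] = {}
    for key, dist in table.items():
        total = sum(dist.values())
        if total == 0:
            continue
        out[key] = max(sorted(dist), key=lambda t: dist[t])
    return out


def load_count_table(source: Union[str, os.PathLike, Iterable[str]]):
    """Read a 4-column count TSV: lemma, pos, event_type, count."""
    if isinstance(source, (str, os.PathLike)):
        with open(source, encoding="utf-8") as fh:
            return load_count_table(list(fh))
    rows = []
    for lineno, raw in enumerate(source, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise ValueError(f"count table line {lineno}: expected 4 columns")
        rows.append((cols[0], cols[1], cols[2], int(cols[3])))
    return rows
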