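# biocompose

Rule-based **biological event composition**: a two-phase, linguistically
grounded pipeline that extracts molecular-biology events — and the
speculation and negation wrapped around them — from text annotated with gold
entity mentions and syntactic dependency parses.

## Who this is for

Biomedical text-mining researchers and practitioners who need an auditable,
training-free event extractor in the BioNLP shared-task mould (GENIA / EPI /
ID style tracks), or a reference implementation of compositional
negation/speculation scope with scalar modality values.

## The model

**Phase 1 — semantic composition.** Per-sentence collapsed typed dependencies
(with conjunct propagation), gold entities and a six-feature trigger lexicon
are transformed into a document-level, directed acyclic **embedding graph**
over surface elements. Transformation rules collapse multi-token mentions,
split coordinations around an explicit conjunction node, invert
modifier-direction dependencies and correct systematic parse errors; adjacent
sentences are linked by PREV arcs and deterministic coreference resolution
(RELAT, APPOS, PRON, DNP classes) adds COREF arcs. The graph is then
traversed bottom-up, composing **predications**

```
Pr := [P, MV, POL, Arg1..n]      MV ∈ [0,1],  POL ∈ {positive, negative, neutral}
```

with Object/Subject/Adjunct arguments assigned by typed rules
⟨relation, POS, inclusions, exclusions⟩, propagated through chains of
semantically free nodes, and distributed over coordinations and plural
anaphora. Scalar operators act on the modality value MV:

* a **negator** inverts it: `MV' = 1 − MV`;
* a **modal** of category strength *s* rescales it:
  `MV' = s·MV` if `MV ≥ 0.5`, else `MV' = MV + (1−s)(1−MV)`
  (so *may*, *s* = 0.7, maps 1 → 0.7 but 0 → 0.3 — hedging a negation
  weakens it);
* polarity composes by a small table in which neutral is transparent and
  negative is absorbing.

**Phase 2 — task mapping.** Predications are converted to standoff event
annotations under track-specific constraints: embedding types map to event or
modification types guarded by polarity/MV conditions (e.g. CAUSAL+neutral →
Regulation, SUCCESS+negative → Negation, SPECULATIVE with MV > 0 →
Speculation), logical arguments map to semantic roles (Object → Theme,
Subject → Cause, with Binding and Process exceptions), and participants or
whole events that violate the event definitions are pruned, cascading through
events that referenced them.

## Worked example

```
$ python examples/extract_events.py
text: Our previous results show that recombinant gp41 stimulates interleukin-10 (IL-10) production in human monocytes.
...
.a2 output:
T4  Positive_regulation 48 58  stimulates
T5  Gene_expression 82 92  production
E1  Positive_regulation:T4 Theme:E2 Cause:T1
E2  Gene_expression:T5 Theme:T2
```

The trigger *production* yields a Gene_expression event with the protein
interleukin-10 as Theme; *stimulates* (a causal embedding trigger with
positive polarity) becomes a Positive_regulation event taking that event as
Theme and the protein gp41 as Cause. The evidential *show* composes a
DEMONSTRATIVE predication, but with positive polarity it is task-irrelevant
and is pruned. `examples/modality_chain.py` prints the modality trajectory of
*may not involve* (1.0 → 0.0 → 0.3), and `examples/coreference.py` shows a
pronoun resolved across a sentence boundary recovering an otherwise
unextractable Theme.

A thin CLI processes directories of `.txt`/`.a1`/`.dep` triples:

```
biocompose INPUT_DIR --out OUT_DIR --track GENIA --coref all
```

with flags for the trigger lexicon, rule tables, coreference-class ablations
and the argument-propagation depth.

## Layout

```
src/biocompose/   model, lexicon, graph, coref, compose, mapping, standoff, cli
src/biocompose/data/   seed lexicon + rule tables (TSV) + hypernym/meronym lists
src/biocompose/fixtures.py   worked-example inputs and the random-tree oracle
examples/         narrative scripts, one per capability
tests/            pytest suite (unit, property, acceptance)
docs/methods.md   the methods note: model, assumptions, design choices
```
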