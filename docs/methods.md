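# Methods

## Model

The package treats event extraction as semantic composition over a
document-level **embedding graph**. Nodes are *surface elements* — tokens or
collapsed contiguous multi-token units — each either bound to an entity
mention, bound to a trigger-lexicon entry, or semantically free. Typed,
directed arcs (*embedding relations*, uppercase labels) encode semantic
dependency direction, which may differ from the syntactic one. Two special
arc types cross sentence boundaries: PREV connects the topmost nodes of
adjacent sentences, COREF connects an anaphor to its antecedent(s). The
non-COREF part of the graph is required to be acyclic.

A **predication** is a predicate plus a scalar modality value MV ∈ [0,1], a
polarity in {positive, negative, neutral}, and an ordered argument list
(Object first, Subject second, adjuncts after). A predication is *atomic*
when all arguments are ontologically simple (entities or free elements) and
*embedding* when at least one argument is itself a predication. *Scope* is
the transitive closure of direct embedding and is a strict partial order.

Embedding trigger types fall into four classes: MODAL (epistemic,
evidential, dynamic, deontic, intentional, interrogative, success),
RELATIONAL (causal, temporal, correlative, comparative, saliency),
ATTRIBUTIVE (a verb like *undergo* that donates its own argument to the
predication it embeds) and VALENCE_SHIFTER (negator, diminisher,
intensifier). MODAL and VALENCE_SHIFTER predicates are *operators*: they
rescale the modality values of predications in their scope. Atomic trigger
types are plain event types (GENE_EXPRESSION, BINDING, ...).

## Assumptions on the input

The pipeline does not parse. It consumes (a) document text, (b) gold entity
mentions with character offsets (0-based, half-open — the standoff
convention), and (c) per-sentence dependency parses in the
collapsed-with-conjunct-propagation style, in one of two auto-detected text
dialects. The CoNLL-style dialect carries lemma and POS per token plus an
optional seventh column of extra `head:label` pairs, because conjunct
propagation gives tokens multiple governors, which single-head CoNLL cannot
express. The relation-line dialect (`label(gov-3, dep-5)`) carries no
lemma/POS; forms are recovered from the mention strings, lemmas default to
the lowercased form and the empty POS acts as a wildcard in lexicon lookup
and rule matching — adequate for structural experiments, whereas file-based
pipelines should use the CoNLL dialect. Token character offsets are
recovered by scanning the document text left to right.

## Trigger lexicon

Each entry has six features: lemma (possibly multi-word), coarse POS,
semantic type, polarity, category strength in [0,1], and a negative-raising
flag. One semantic type per (lemma, POS) — the lexicon avoids sense
disambiguation; ambiguous triggers harvested from count data are resolved by
maximum likelihood with a lexicographic tie-break, and all-zero triggers are
dropped. Defaults for blank columns: neutral polarity, strength 1.0, no
raising. Matching in text is greedy, longest-first, left-to-right with no
overlaps; multi-word entries match on their lemma sequence, single-word
entries also check the coarse POS. A small prefix table (non-, un-, in- →
negative; up- → positive; down- → negative) overrides polarity when the
stripped lemma is itself in the lexicon. The shipped seed lexicon (~70
entries) covers the triggers exercised by the built-in fixtures; it is a
starting point, not a substitute for a corpus-scale dictionary, and larger
dictionaries load from the same TSV format.

## Graph construction

Five transformation rules apply per sentence in a fixed priority order —
corrective, collapse, split, invert, identity — because corrections must
precede the rules that consume the corrected dependencies:

1. *corrective* (modifier coordination): `conj_X(A, H)` with `nn(H, M)`
   rewrites to `NN(H, x)`, `CC(x, A)`, `CC(x, M)` around the conjunction
   node x;
2. *collapse*: every multi-token entity or trigger mention becomes one node;
   dependencies internal to the unit vanish, external ones reattach
   (entities win overlaps with triggers);
3. *split*: `conj_X(A, B), conj_X(A, C)` becomes `CC(x, A), CC(x, B),
   CC(x, C)`; the conjunction node is the `cc` dependent when present, else
   a synthesised node; conjunction nodes are grammatically plural;
4. *invert*: modifier dependencies (amod, advmod, aux, auxpass, neg, det,
   partmod, mark) whose dependent is a bound trigger flip direction; several
   such modifiers of one head chain in token order, producing e.g.
   `ADVMOD(Thus, may), AUX(may, not), NEG(not, involve)`;
5. *identity*: any remaining dependency passes through with its label
   uppercased.

The rule engine is data-driven ((name, action, params) records), so further
rules are configuration. If a transformed sentence graph is cyclic, the arc
whose dependent has the latest character offset is dropped, with a warning,
until the graph is a DAG. The topmost node of a sentence is the one with no
incoming intra-sentential arc; among several roots the earliest offset wins,
and isolated stray tokens (function words absent from the dependency list)
are never preferred over connected roots.

## Coreference

Four deterministic classes, each independently switchable (the CLI exposes
them for ablations):

* **RELAT** — `REL(X, RP) ∧ RCMOD(ANT, X) ⇒ COREF(RP, ANT)`;
* **APPOS** — arcs in {APPOS, ABBREV, PREP_INCLUDING, PREP_SUCH_AS} yield a
  COREF arc normalised so the anaphor is the later mention;
* **PRON** — third-person personal/possessive pronouns only; candidates must
  agree in person and number. Number is read from POS and lemma; verbal
  triggers have undefined number and therefore never agree, which keeps
  pronouns from resolving to verbs — this package's reading of the
  agreement requirement;
* **DNP** (sortal anaphora) — definite/demonstrative NPs not bound to
  entities; number agreement plus at least one semantic constraint: head-word
  identity, singular hypernymy (hypernym head + entity antecedent), plural
  hypernymy (set-instance anaphora over a conjunction), meronymy (meronym
  head + conjunction), or the event constraint. The event constraint —
  anaphor and antecedent lexicalise the same event — is deliberately narrow:
  same lexicon semantic type and same lemma stem (a small suffix-stripping
  stemmer), rather than any broader notion of event identity.

Candidate antecedents are prior nodes in the anaphor's paragraph
(paragraphs are blank-line-delimited; an abstract is one paragraph) that are
semantically bound, hypernym-headed, or conjunctions. Three structural
blockers apply: direct embedding either way; subject-antecedent with
object-anaphor of the same relation unless the anaphor is reflexive; and
subject-antecedent with adjunct-anaphor. The surviving candidate closest in
the graph is selected — shortest undirected path over intra-sentential +
PREV arcs, ties broken by character distance, then by earlier offset (the
distance metric is this package's choice; only "closest in the graph" is
inherent to the method). A plural anaphor resolving to a conjunction
receives one COREF arc per conjunct. The free-antecedent restriction is
faithful to the method and reproduces its known failure mode: when the true
antecedent is semantically free, a more distant bound mention is chosen
(the built-in PKD fixture demonstrates this).

## Composition

Nodes are processed children-first (reverse topological order on the
non-COREF graph, lexicographic by document position for determinism). At
each trigger-bound node:

1. **Argument identification.** For each outgoing relation, the first rule
   in file order whose relation type, predicate POS and constraints match
   assigns Object/Subject/Adjunct; at most one Object and one Subject per
   predication (first wins). A rule's constraint is satisfied when the
   predicate's lemma or semantic type is in the set; the test applied is
   `(IN empty ∨ satisfies(IN)) ∧ ¬satisfies(EX)`, the reading under which
   inclusion lists actually restrict.
2. **Resolution.** An entity child contributes its mention; a trigger child
   contributes its predication(s); an anaphor is substituted by its
   antecedent(s); a conjunction contributes all conjuncts; a free child
   triggers **argument propagation** — breadth-first search through chains
   of semantically free nodes, optionally depth-limited (depth counts free
   nodes on the path), the closest bound descendant winning with earlier
   offset as tie-break; if none is found the free element itself is kept as
   an entity of unknown type. Default propagation depth is unlimited;
   depth 1 is exposed as a precision-oriented configuration.
3. **Distribution.** Multi-valued Object/Subject slots (coordination, plural
   anaphora) produce one predication per value, all other slots shared;
   multi-valued adjunct slots flatten into several adjunct arguments.
4. **Polarity.** Atomic predications take their trigger's polarity;
   embedding ones compose trigger polarity with the embedded predication's
   polarity (Object-position predication preferred): neutral is transparent,
   negative absorbing, positive flips only over negative.
5. **Modality.** Atomic predications start at MV 1.0. A NEGATOR inverts its
   *directly embedded* predication(s) (`1 − MV`), marks them negated and
   makes their polarity negative; if the target predicate licenses negative
   raising (*think*, *believe*), the inversion transfers to the target's
   complement instead. A MODAL/DIMINISHER/INTENSIFIER rescales the nearest
   *non-operator* predications in its scope — operators are skipped, so in
   *may* ≻ *not* ≻ *involve* the modal rescales *involve* (0 → 0.3), not
   the negator. An operator predication records as its own MV the value it
   imposed on its first target, matching the convention in which a
   modal predication prints the value it contributes (0.7 for a
   strength-0.7 modal over a default complement). Because inner operators
   are processed first, stacked operators apply outermost-last. A negator
   with no predication argument (determiner negation: *no NF-κB bound*)
   negates the predications that take its entity/free descendants as
   arguments, reached without crossing another predicate node. MV is
   clamped to [0,1] after every operator as a safety net; every shipped
   operator already preserves the interval.

Predication ids are assigned after traversal in document order, so output is
reproducible run to run. Forward references (a relative pronoun whose
antecedent predication is composed after its consumer) are patched in after
the traversal; the scalar values of the consumer are not recomputed.

## Mapping

Three steps per track (GENIA, EPI, ID):

1. **Type mapping** — first matching row of a (tracks, predication type,
   polarity, MV-constraint → output) table; atomic predications keep their
   event type. The shipped table contains the documented core rows plus
   extension rows marked `# extension` in the TSV, added for consistency
   with the worked examples: CAUSAL+positive → POSITIVE_REGULATION and
   CAUSAL+negative → NEGATIVE_REGULATION (GENIA/ID), ASSUMPTIVE with MV > 0
   → SPECULATION, EPISTEMIC+negative → SPECULATION, DEDUCTIVE+positive with
   MV > 0 → SPECULATION.
2. **Role mapping** — Object → Theme (Participant for PROCESS, Scope for
   SPECULATION/NEGATION), Subject → Cause (Theme for BINDING); the shipped
   file orders constrained rows before generic ones so that first-match
   semantics realises the exceptions. Unmatched arguments carry no role and
   fall to pruning.
3. **Pruning** — drop participants whose role the event definition does not
   allow, semantically free participants, predications with unmappable
   types, and events lacking their mandatory participant — except PROCESS
   (ID track), which may keep zero participants. Removals cascade: an event
   referencing a dropped sub-event loses that participant and is re-tested.

Speculation and Negation are emitted as modification annotations on the
*innermost mapped events* within the operator's scope (every frontier event
if several); an event whose predication was inverted by a negator receives a
Negation mark directly. A SUCCESS-negative predication and a negator can in
principle both mark one event; both modifications are emitted and the
composed MV decides the polarity reading — the interaction is left visible
rather than collapsed. Event definitions (allowed and mandatory roles per
type and track) ship as a TSV covering the event types the fixtures
exercise; they are configuration, not code.

Output is standoff `.a2`: trigger T lines numbered after the `.a1` maximum,
E lines in document order of the trigger, repeated roles numbered Theme,
Theme2, ..., M lines after the events. Writing refuses dangling references,
and byte-identical output across runs is a tested invariant.

## Synthetic fixtures and what the tests show

The fixture module encodes the worked examples as self-contained documents
(text, entities, parses, expectations); parses printed in the source
material are transcribed, the rest are authored by hand and marked as such,
with sentences sometimes shortened around the phenomenon. The random
generator produces embedding *trees* (≤ 12 nodes, single parent per node)
of entity/trigger/free nodes with rule-matching arc labels and
modal/negator decorations; trees keep operator application order
unambiguous. The independent oracle is a direct post-order recursive
evaluator of the argument-identification, propagation, polarity and modality
definitions, with propagation done by exhaustive path enumeration; it
assumes no negative raising (the generator guarantees this) and no
coordination or coreference, which the worked-example fixtures cover
instead. Composer-oracle agreement is checked over 1000 seeded graphs.

Passing these tests shows the calculus and the plumbing are implemented as
specified on clean, correctly parsed input. It does not show corpus-level
accuracy: real parses are noisy, real trigger inventories are far larger,
and the corpus-scale benchmark figures require shared-task data and lexicon
resources that are not reproducible at desk scale, so no corpus F-scores are
claimed. The acceptance script reports only quantities the package computes
at run time (the modality values of the negated modal chain, sizes 2–3
nodes).

## Known limitations

* Quantifiers are ignored (*any of these receptors* distributes over all
  conjuncts — reproduced as-is, not corrected).
* Only core participants (Theme, Cause, Participant, Scope) are mapped; no
  Site/AtLoc/ToLoc roles and no named-entity recognition beyond the gold
  `.a1` entities.
* Copular constructions have no dedicated argument rules.
* The transformation-rule set implements the four documented classes plus
  identity; further hand-crafted rules must be supplied as configuration.
* The seed lexicon is example-scale; recall on real text is bounded by
  lexicon coverage by construction.
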