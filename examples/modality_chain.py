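"""Scalar modality composition over a negated modal chain.

Builds the sentence fragment "may not involve ... activation" from its
dependency parse, composes predications bottom-up, and prints how the
negator and the speculative modal move the modality value of the embedded
predication.  mv=1 means the predication holds at full strength on its modal
scale, mv=0 means it is negated; 'may' (category strength 0.7) pulls values
toward the middle of the scale from either side.
"""

from biocompose.compose import CompositionConfig, compose_document
from biocompose.coref import resolve_all
from biocompose.fixtures import case
from biocompose.graph import build_document_graph
from biocompose.standoff import align_tokens, default_argument_rules, default_lexicon

c = case("ex12")   # "Thus, IL-10 upregulation in monocytes may not involve NF-kB activation."
print("text:", c.doc.text, "\n")

sents = align_tokens(c.doc.text, c.doc.sentences)
graph = build_document_graph(sents, c.doc.entities, default_lexicon())
resolve_all(graph)
preds = compose_document(graph, default_argument_rules(), CompositionConfig())

for p in preds:
    print(f"  {p.predicate.lemma:>14s}  {p.semantic_type:<20s} "
          f"mv={p.mv:<4g} polarity={p.polarity}"
          + ("  [negated]" if p.negated else ""))

involve = next(p for p in preds if p.predicate.lemma == "involve")
print(f"\nThe 'involve' predication starts at the default mv 1.0, the negator"
      f"\ninverts it to 0.0, and the modal rescales it to {involve.mv:g}:"
      f"\nthe involvement is denied, but only weakly (hedged by 'may').")
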