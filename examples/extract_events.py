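"""End-to-end event extraction into BioNLP standoff format.

Takes a sentence with gold protein mentions and its dependency parse, runs
the two-phase pipeline (semantic composition, then task mapping) and prints
the resulting .a2 annotations: T lines are event triggers, E lines are events
with role-bound participants, M lines mark speculation/negation.
"""

from biocompose.fixtures import case
from biocompose.standoff import PipelineConfig, process_document, write_a2

for name in ("ex14", "ex7"):
    c = case(name)
    print("text:", c.doc.text)
    for e in c.doc.entities:
        print(f"  {e.id} {e.semantic_type} {e.char_span}: {e.text}")
    result = process_document(c.doc, PipelineConfig(track=c.track))
    print("\n.a2 output:")
    print(write_a2(result.events, result.modifications, c.doc.max_t_index))

print("In the first document, 'stimulates' becomes a Positive_regulation "
      "event whose Theme is the Gene_expression event of 'production' and "
      "whose Cause is the protein gp41. In the second, 'failed to stimulate' "
      "additionally yields a Negation mark (M1) on the regulation event.")
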