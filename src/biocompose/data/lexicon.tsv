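# Seed trigger dictionary: lemma	pos	semantic_type	polarity	category_strength	negative_raising
# Embedding predicates (modal / relational / attributive / valence shifter)
show	VB	DEMONSTRATIVE	positive	1.0	false
demonstrate	VB	DEMONSTRATIVE	positive	1.0	false
suggest	VB	DEDUCTIVE	positive	0.6	false
unknown	JJ	EPISTEMIC	negative	0.7	false
think	VB	EPISTEMIC	positive	0.5	true
believe	VB	EPISTEMIC	positive	0.6	true
presume	VB	ASSUMPTIVE	positive	0.7	false
assume	VB	ASSUMPTIVE	positive	0.7	false
may	MD	SPECULATIVE	positive	0.7	false
might	MD	SPECULATIVE	positive	0.6	false
possible	JJ	SPECULATIVE	positive	0.6	false
appear	VB	SPECULATIVE	positive	0.7	false
capable	JJ	POTENTIAL	positive	1.0	false
unable	JJ	POTENTIAL	negative	1.0	false
should	MD	OBLIGATIVE	positive	0.7	false
try	VB	INTENTIONAL	positive	1.0	false
examine	VB	INTERROGATIVE	neutral	1.0	false
fail	VB	SUCCESS	negative	1.0	false
induce	VB	CAUSAL	positive	1.0	false
lead	VB	CAUSAL	positive	1.0	false
cause	VB	CAUSAL	positive	1.0	false
mediate	VB	CAUSAL	neutral	1.0	false
stimulate	VB	CAUSAL	positive	1.0	false
prevention	NN	CAUSAL	negative	1.0	false
prevent	VB	CAUSAL	negative	1.0	false
effect	NN	CAUSAL	neutral	0.5	false
role	NN	CAUSAL	neutral	0.5	false
thus	RB	CAUSAL	neutral	1.0	false
coincide	VB	CORRELATIVE	neutral	0.5	false
correlate	VB	CORRELATIVE	neutral	0.5	false
compare	VB	COMPARATIVE	neutral	1.0	false
important	JJ	SALIENCY	positive	1.0	false
subsequent	JJ	TEMPORAL	neutral	1.0	false
involve	VB	PATIENT	neutral	1.0	false
involvement	NN	PATIENT	neutral	1.0	false
require	VB	PATIENT	neutral	1.0	false
undergo	VB	PATIENT	neutral	1.0	false
not	RB	NEGATOR	negative	1.0	false
no	DT	NEGATOR	negative	1.0	false
absence	NN	NEGATOR	negative	1.0	false
lack	VB	NEGATOR	negative	1.0	false
weakly	RB	DIMINISHER	neutral	1.0	false
slightly	RB	DIMINISHER	neutral	0.7	false
barely	RB	DIMINISHER	neutral	0.5	false
strongly	RB	INTENSIFIER	neutral	0.8	false
# Atomic predicates (event-typed triggers)
stimulation	NN	POSITIVE_REGULATION	neutral	1.0	false
activate	VB	POSITIVE_REGULATION	neutral	1.0	false
activation	NN	POSITIVE_REGULATION	neutral	1.0	false
increase	VB	POSITIVE_REGULATION	neutral	1.0	false
upregulation	NN	POSITIVE_REGULATION	positive	1.0	false
reduce	VB	NEGATIVE_REGULATION	negative	1.0	false
regulation	NN	REGULATION	neutral	1.0	false
transcriptional regulation	NN	REGULATION	neutral	1.0	false
expression	NN	GENE_EXPRESSION	neutral	1.0	false
express	VB	GENE_EXPRESSION	neutral	1.0	false
overexpression	NN	GENE_EXPRESSION	positive	1.0	false
regulate	VB	REGULATION	neutral	1.0	false
production	NN	GENE_EXPRESSION	neutral	1.0	false
transcription	NN	TRANSCRIPTION	neutral	1.0	false
phosphorylation	NN	PHOSPHORYLATION	neutral	1.0	false
phosphorylate	VB	PHOSPHORYLATION	neutral	1.0	false
degradation	NN	PROTEIN_CATABOLISM	neutral	1.0	false
bind	VB	BINDING	neutral	1.0	false
binding	NN	BINDING	neutral	1.0	false
interaction	NN	BINDING	neutral	1.0	false
engagement	NN	BINDING	neutral	1.0	false
localization	NN	LOCALIZATION	neutral	1.0	false
methylation	NN	METHYLATION	neutral	1.0	false
colonization	NN	PROCESS	neutral	1.0	false
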