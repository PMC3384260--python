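# Argument identification rules: relation_type	POS	inclusions	exclusions	arg_type
# First matching rule (file order) wins per relation; constraints test the
# predicate's lemma or semantic type.
PREP_ON	NN	influence,impact,effect	-	Object
AGENT	VB	-	-	Subject
NSUBJPASS	VB	-	-	Object
WHETHER_COMP	VB	INTERROGATIVE	-	Object
PREP_IN	NN	-	effect,role,influence,importance	Adjunct
# extension rows: general verbal/nominal argument realisations
DOBJ	VB	-	-	Object
XCOMP	VB	-	-	Object
CCOMP	VB	-	-	Object
XCOMP	MD	-	-	Object
NSUBJ	VB	-	-	Subject
NSUBJ	JJ	-	-	Subject
XSUBJ	-	-	-	Subject
PREP_OF	NN	-	-	Object
PREP_TO	VB	-	-	Object
PREP_TO	NN	-	-	Object
PREP_FOR	JJ	-	-	Object
NN	NN	-	-	Object
POSS	NN	-	-	Object
AMOD	JJ	-	-	Object
ADVMOD	-	-	-	Object
AUX	-	-	-	Object
NEG	-	-	-	Object
DET	DT	-	-	Object
ACOMP	VB	-	-	Object
PREP_IN	VB	-	-	Adjunct
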