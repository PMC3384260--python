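# Type mapping: tracks	predication_type	polarity	mv_constraint	output
# First matching rule (file order) wins.
GENIA,ID	CAUSAL	neutral	-	REGULATION
GENIA,ID,EPI	SUCCESS	negative	-	NEGATION
EPI	CAUSAL	positive	-	CATALYSIS
GENIA,ID,EPI	SPECULATIVE	-	>0.0	SPECULATION
GENIA,ID,EPI	DEMONSTRATIVE	negative	-	SPECULATION
# extension rows (consistent with the worked examples; not in the core table)
GENIA,ID	CAUSAL	positive	-	POSITIVE_REGULATION
GENIA,ID	CAUSAL	negative	-	NEGATIVE_REGULATION
GENIA,ID,EPI	ASSUMPTIVE	-	>0.0	SPECULATION
GENIA,ID,EPI	EPISTEMIC	negative	-	SPECULATION
GENIA,ID,EPI	DEDUCTIVE	positive	>0.0	SPECULATION
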