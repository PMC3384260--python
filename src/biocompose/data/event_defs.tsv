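# Event definitions per track: track	event_type	allowed_roles	mandatory_roles
GENIA	GENE_EXPRESSION	Theme	Theme
GENIA	TRANSCRIPTION	Theme	Theme
GENIA	PROTEIN_CATABOLISM	Theme	Theme
GENIA	PHOSPHORYLATION	Theme	Theme
GENIA	LOCALIZATION	Theme	Theme
GENIA	BINDING	Theme	Theme
GENIA	REGULATION	Theme,Cause	Theme
GENIA	POSITIVE_REGULATION	Theme,Cause	Theme
GENIA	NEGATIVE_REGULATION	Theme,Cause	Theme
ID	GENE_EXPRESSION	Theme	Theme
ID	TRANSCRIPTION	Theme	Theme
ID	PROTEIN_CATABOLISM	Theme	Theme
ID	PHOSPHORYLATION	Theme	Theme
ID	LOCALIZATION	Theme	Theme
ID	BINDING	Theme	Theme
ID	REGULATION	Theme,Cause	Theme
ID	POSITIVE_REGULATION	Theme,Cause	Theme
ID	NEGATIVE_REGULATION	Theme,Cause	Theme
ID	PROCESS	Participant	-
EPI	CATALYSIS	Theme,Cause	Theme
EPI	METHYLATION	Theme	Theme
EPI	PHOSPHORYLATION	Theme	Theme
EPI	GENE_EXPRESSION	Theme	Theme
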