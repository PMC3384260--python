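# Role mapping: logical_arg	constrained_to	exclusions	role
# First matching rule (file order) wins; constrained rows precede generic ones.
Object	SPECULATION,NEGATION	-	Scope
Object	PROCESS	-	Participant
Object	-	PROCESS	Theme
Subject	BINDING	-	Theme
Subject	-	BINDING	Cause
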