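# Post-processing exclusion rulebook: rule_id<TAB>field<TAB>pattern<TAB>category
# field is "match" or "context_string"; patterns are case-insensitive Python
# regular expressions.  Any machine-labelled positive whose mention matches a
# rule is vetoed (relabelled non_true_event).  User-replaceable.
heading_line	context_string	(?m)^\W*(?:[a-z0-9][\).])?[ \t]*(?:history of[ \t]+)?(?:previous[ \t]+|past[ \t]+)?suicide[ \t]+attempts?(?:[ \t]*/[ \t]*(?:ideation|self[- ]?harm))?(?:[ \t]+history)?[ \t]*[x*:0-9]*[ \t]*$	title_neutral
questionnaire_item	context_string	have[ \t]+you[ \t]+ever[ \t]+(?:attempted|tried[ \t]+to|made[ \t]+an[ \t]+attempt)	title_neutral
history_of_previous	context_string	history[ \t]+of[ \t]+(?:previous|prior)[ \t]+suicide[ \t]+attempts?	title_neutral
ambiguous_previously_also	context_string	previously[ \t]+also[ \t]+attempted[ \t]+to\b	ambiguous
negation_before_match	context_string	\b(?:no|not|never|without|nil|denies|denied|didn.?t|doesn.?t|wouldn.?t|won.?t)(?:[ \t]+[^\s.!?;]+){0,4}[ \t]+[^\s.!?;]*(?:attempt|overdos)	negation_before_match
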