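# Phrase-scope negation gazetteer for the suicide-ideation rules.
# Multi-token negating phrases; same sentence-level veto as the first list.
# User-replaceable: supply your own file via IdeationRuleConfig or the CLI.
would not
didn't
does not
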