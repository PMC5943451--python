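# Sentence-scope negation gazetteer for the suicide-ideation rules.
# Any hit anywhere in the sentence vetoes the ideation mention.
# User-replaceable: supply your own file via IdeationRuleConfig or the CLI.
no
not
nil
denie*
denied
without
never
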