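# Seed dictionary of suicide-attempt surface patterns (prefix wildcards with *).
# A replacement for site-specific attempt lexicons; extend freely with local
# recording habits (typos, abbreviations, idioms).
suicide attempt*
attempt* suicide
attempted suicide
attempt* to end her life
attempt* to end his life
attempt* to kill himself
attempt* to kill herself
attempt* to take her life
attempt* to take his life
attempt* to end it all
overdose
overdosed
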