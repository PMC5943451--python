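# Assertion trigger lexicon: pattern<TAB>category<TAB>max_scope
# Categories: negation_pre, negation_post, historical, hypothetical,
# experiencer, termination.  max_scope counts tokens; forward for pre
# triggers, backward for post triggers.  Seeded from the published ConText
# default term lists; user-replaceable.
no	negation_pre	5
not	negation_pre	5
never	negation_pre	5
without	negation_pre	5
denies	negation_pre	5
denied	negation_pre	5
denying	negation_pre	5
denie*	negation_pre	5
didn't	negation_pre	5
doesn't	negation_pre	5
wouldn't	negation_pre	5
cannot	negation_pre	5
no evidence of	negation_pre	5
no sign of	negation_pre	5
negative for	negation_pre	5
rather than	negation_pre	5
ruled out	negation_pre	5
nil	negation_pre	5
was ruled out	negation_post	5
unlikely	negation_post	5
history of	historical	999
history	historical	999
past	historical	999
previous	historical	999
previously	historical	999
prior	historical	999
years ago	historical	999
year* ago	historical	999
months ago	historical	999
in the past	historical	999
childhood	historical	999
if	hypothetical	999
in case	hypothetical	999
should she	hypothetical	999
should he	hypothetical	999
risk of	hypothetical	999
mother	experiencer	999
father	experiencer	999
brother	experiencer	999
sister	experiencer	999
son	experiencer	999
daughter	experiencer	999
husband	experiencer	999
wife	experiencer	999
partner	experiencer	999
friend	experiencer	999
aunt	experiencer	999
uncle	experiencer	999
grandmother	experiencer	999
grandfather	experiencer	999
cousin	experiencer	999
neighbour	experiencer	999
family member	experiencer	999
but	termination	1
however	termination	1
although	termination	1
though	termination	1
except	termination	1
apart from	termination	1
which	termination	1
presents	termination	1
presented	termination	1
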