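# Methods

`suicidality-nlp` re-implements two clinical-text classifiers for psychiatric
EHR free text — a rule-based detector of *recorded suicidal ideation* and a
hybrid machine-learning + rule-based detector of *recorded suicide attempts* —
together with the evaluation harness and a synthetic note generator that makes
every stage testable without access to real patient records.

## The two classifiers

**Ideation (rules).** Clinicians record ideation with highly standardised
language, so detection is a same-sentence co-occurrence rule: a token matching
`suicid*` followed by a token matching `ideat*` (prefix wildcards; order
required by default, adjacency not, so "suicidal thoughts and ideation" still
matches). Classification is a sentence-scope veto: if any entry of either of
two negation gazetteers occurs anywhere in the sentence, the mention is
`non_true_event`; otherwise `true_event`. Both gazetteers ship as replaceable
plain-text files ({no, not, nil, denie\*, denied, without, never} and
{would not, didn't, does not}); the mechanism, not the particular word list,
is the contract.

**Attempt (hybrid).** Attempts are recorded in many surface forms, so the
pipeline starts from a replaceable attempt-term dictionary (wildcarded
patterns such as `suicide attempt*`, `attempt* to end her life`, `overdose`).
Every dictionary hit becomes a mention carrying two output fields: `match`
(the hit text) and `context_string` (an excerpt of up to 500 characters built
from the whole sentences nearest the hit, hard-truncated centred on the match
if a single region exceeds the budget). Each mention is classified by a
linear SVM over bag-of-words features — token stems (classic Porter suffix
stripping), stem+POS pairs, and three binary assertion flags — computed over
up to six sentence windows around the concept sentence *s*:
{s}, {s−1,s}, {s,s+1}, {s−1,s,s+1}, {s−2..s}, {s..s+2}, clipped at document
edges and deduplicated. At prediction time every window is scored and the
window with the highest calibrated confidence decides the label (ties to the
smallest window id); the confidence `max(p, 1−p)` is the probability the
record was classified correctly, which also drives `rank_for_review` (the
lowest-confidence records are the ones worth manual re-annotation).

**Assertion flags (ConText-style).** A trigger lexicon (TSV, replaceable)
marks negation, historical, hypothetical and experiencer cues. Pre-triggers
project forward, post-triggers backward; a scope closes at the sentence end,
at a termination trigger ("but", "however", ...) or after `max_scope` tokens.
Defaults follow the published ConText conventions: 5 tokens for negation,
whole sentence for historical/experiencer. Hypothetical triggers set the
same "temporally irrelevant" flag as historical ones, since the output
vocabulary is three flags (negated / historical / experiencer-other).
Scopes never cross sentence boundaries.

**Post-processing filters.** Bag-of-words models over-call *neutral*
occurrences of attempt terms — questionnaire items ("Have you ever attempted
suicide?"), bare subheadings ("Past suicide attempts", "b) Suicide attempts
x"), ambiguous fragments ("previously also attempted to") and negated
statements ("she would not attempt to take her life"). A rulebook of
case-insensitive regular expressions over the two mention fields vetoes any
machine-labelled positive matching a rule, with a per-rule exclusion log.
Filtering is a distinct post-stage rather than a training-time fix, so the
rulebook can be tuned per site without retraining. The negation rule requires
the negating token within 5 tokens before the attempt term (aligned with the
assertion scope default) and does not cross sentence punctuation.

## Training procedure

The grid is {stop-word removal on/off} × {SVM cost C ∈ {0.1, 1, 10}} — a
linear kernel only, the standard choice for sparse bags of words. Each cell
is scored by stratified 5-fold cross-validated F1 (folds shuffled under the
run seed; the fold count drops automatically if the minority class is
smaller than 5). The best-F1 cell (ties to the first cell in grid order) is
refit on all training data. Probabilities come from a Platt sigmoid
`p = 1/(1+exp(A·f+B))` fitted by the Lin–Weng–Keerthi Newton method on
*out-of-fold* decision scores, so calibration never sees its own training
fit. Training features use the ±1 three-sentence window by default
(`train_window_id=4`, configurable). Models persist as deterministic JSON
(vocabulary, weights, bias, calibration, config snapshot and a SHA-256
fingerprint of the featurised training set); save→load→save is
byte-identical.

Single-class training sets and empty grids raise errors rather than
degenerate models. Mentions containing only unseen vocabulary are scored
from the bias with calibrated confidence, never an error.

## Evaluation conventions

Confusion counts use the classifier-rows × gold-columns layout
(`a` = both true, `b` = classifier-false/gold-true, `c` =
classifier-true/gold-false, `d` = both false); precision = a/(a+c),
recall = a/(a+b). Metrics are exact rationals internally and display as
one-decimal percentages (round-half-up); zero denominators are marked
undefined, never silently zeroed. Note one display consequence: the fixture
with a=265, b=37, c=24, d=174 has recall 265/302 = 87.748…%, which renders
as 87.7% at one decimal (87.75% at two). Cohen's kappa uses
marginal-product chance agreement with exact arithmetic; identical constant
ratings define κ = 1, any other p_e = 1 degeneracy is marked undefined.
Three-annotator studies are summarised as the set of pairwise kappas plus
their mean (`cohens_kappa` is strictly two-rater). Evaluation is
mention-level; `patient_rollup` provides the document-independent
"ever-event" per-patient flag that downstream epidemiology consumes.

## The synthetic corpus — what it does and does not show

Because the source EHR data are access-restricted, the generator emulates
the *mention taxonomy* such corpora exhibit: affirmed/negated ideation,
affirmed/negated attempts, neutral titles and questionnaire items,
historical mentions, other-experiencer mentions, self-harm explicitly
without intent, and filler. Documents are one sentence per line (newlines
are sentence boundaries, which is also how headings become their own
sentences in real notes). Default conditions: 500 documents, 0.55/0.45
event/correspondence mix, 3–8 sentences per document, and category weights
that put the neutral-title share of attempt-term mentions above 30% — the
documented burden that motivates the post-processing stage. Affirmed
sentences always contain a packaged dictionary term, so detector recall on
synthetic truth is structurally 1, and ideation sentences are constructed to
agree with the packaged negation gazetteers, so rule-oracle agreement is
exact *by construction*. Generation is byte-deterministic per seed.

Passing tests on this corpus therefore demonstrate that the machinery is
correct (detection, scoping, windowing, training, calibration, filtering,
scoring), **not** that the classifiers would reach any particular precision
or recall on real clinical notes: real text has typos, abbreviations,
layout noise, and lexical variety the templates deliberately lack. The
published-table reproductions exercise only the evaluation arithmetic.

A planted-keyword variant generates corpora whose label depends on a single
token; training must place that token's weight in the top decile of weight
magnitudes (verified over 10 seeds), a parameter-recovery check on the
whole feature/SVM path.

The pre/post-filter experiment trains the SVM on narrative attempt mentions
only and then applies it to the full mention stream including the
neutral-title burden. That reproduces the operating regime the filters were
designed for (a classifier that over-calls neutral mentions); measured on
one seeded run, precision roughly doubles while recall is unchanged.
Historical and other-experiencer errors survive the filters by design — the
rulebook targets titles, questionnaires and negation, not temporality.

## Numerical and design choices

* Character offsets are 0-based half-open everywhere; every sentence and
  token span slices the source text to exactly its surface (fuzz-tested).
* The tokenizer takes maximal alphanumeric runs (internal apostrophes kept,
  so "didn't" is one token) plus standalone punctuation.
* The stemmer is the classic Porter algorithm, validated against its
  published worked examples; the POS tagger is a deterministic
  lexicon + suffix tagger over Penn-style tags. Downstream code treats tags
  as opaque feature strings, so the contract is determinism and one tag per
  token, not tagging accuracy.
* Sentence splitting is rule-based (punctuation + newline heuristics), not
  model-based: clinical notes arrive in arbitrary layouts and a
  heading-line-as-sentence behaviour is required for the neutral filters.
  No abbreviation handling ("Dr. Smith" splits); acceptable for the
  line-oriented notes this targets.
* The six window specs are symmetric around the concept sentence and all
  contain it; at a document edge they clip and deduplicate (a mention in
  the first sentence of a long document yields 3 distinct windows).
* `context_string` grows by whole nearest sentences until the budget (500
  characters) would be exceeded, then hard-truncates centred on the match.
  A truncation can in principle leave a line fragment that resembles a
  heading; with 500-character budgets and short clinical sentences this is
  rare, but it is a known sharp edge of regex-over-excerpt filtering.
* Gazetteer matching folds case by default (clinical notes mix case
  freely); a per-file directive switches exact matching on.

## Known limitations

* The packaged lexicons (negation gazetteers, attempt dictionary, trigger
  lexicon, exclusion rulebook) are seed replacements assembled from the
  quoted exemplars of the phenomena they target, not a validated clinical
  vocabulary; real deployments must extend them from local recording
  practice.
* No spelling correction, abbreviation expansion, or temporal reasoning;
  historical scoping is lexical only.
* The ideation rule cannot see paraphrases ("wants to die") by design —
  it trades recall of rare phrasings for precision on the standard term.
* Self-harm-without-intent is separated from attempts only insofar as the
  negation cues and filters catch it; ambiguous narratives will leak.
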