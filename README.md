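# suicidality-nlp

Tools for finding *recorded* suicidal ideation and suicide attempts in
psychiatric EHR free text, for researchers doing suicide-prevention
epidemiology on clinical databases where this information lives in narrative
notes rather than structured fields.

Two classifiers are provided:

* **Ideation — rule-based.** A sentence containing a token matching
  `suicid*` followed by one matching `ideat*` is an ideation mention
  (clinicians record the standard phrase "suicidal ideation" with little
  variation). Two replaceable negation gazetteers veto the mention at
  sentence scope: label = `non_true_event` iff a negation term occurs in the
  sentence, else `true_event`.

* **Attempt — hybrid SVM + rules.** A replaceable dictionary of wildcarded
  attempt terms proposes mentions; each is classified by a linear SVM over
  stems, stem+POS pairs and three ConText-style assertion flags (negated,
  historical, other-experiencer), computed over up to six sentence windows
  around the concept sentence — the window with the highest Platt-calibrated
  confidence decides. A post-processing rulebook then vetoes machine
  positives that are questionnaire items, bare subheadings ("Past suicide
  attempts"), ambiguous fragments or negated-before-the-term statements,
  using the mention's `match` and ~500-character `context_string` fields.

Evaluation uses the 2×2 confusion layout (a, b, c, d = classifier×gold) with
precision a/(a+c), recall a/(a+b) as exact rationals, Cohen's κ =
(p_o − p_e)/(1 − p_e) for annotator agreement, and a per-patient
"ever-event" rollup. Because the motivating EHR corpus is access-restricted,
the package ships a seeded synthetic note generator covering the full
mention taxonomy (affirmed/negated ideation and attempts, neutral titles,
historical, other-experiencer, self-harm-without-intent), so the whole
pipeline runs and is tested end to end on generated data. See
`docs/methods.md` for the model details and what synthetic results do and do
not show.

## Worked example

```python
from suicidality_nlp import *

# a seeded synthetic corpus with gold labels
docs, gold, manifest = generate(SyntheticConfig(n_docs=500, seed=7))
mentions, labels = run_ideation(docs)
print("documents:", len(docs), "| ideation mentions:", len(mentions))
print("first mention:", mentions[0].match, "->", labels[0].label)

# score the rules against generator truth on the rule categories
gold_sent = {(r.doc_id, r.sentence_index): r.label
             for r in manifest
             if r.concept == "ideation"
             and r.category in ("affirmed_ideation", "negated_ideation")}
pred = {}
for m, c in zip(mentions, labels):
    k = (m.doc_id, m.sentence_index)
    if k in gold_sent:
        pred[k] = c.label
report = precision_recall(confusion(gold_sent, pred))
print("rule-oracle precision:", format_percent(report.precision),
      "recall:", format_percent(report.recall), "n =", report.n)
```

prints

```
documents: 500 | ideation mentions: 128
first mention: suicidal ideation -> non_true_event
rule-oracle precision: 100.0% recall: 100.0% n = 110
```

500 generated documents contain 128 sentences matching the ideation rule;
on the 110 mentions from the affirmed/negated-ideation categories the rules
recover the generator's ground truth exactly (they are built from the same
negation lexicons — this checks the machinery, not clinical accuracy). The
evaluation arithmetic itself can be exercised on any confusion fixture:

```python
g, p = make_gold_fixture(ConfusionMatrix(a=265, b=37, c=24, d=174), seed=1)
r = precision_recall(confusion(g, p))
print(format_percent(r.precision), format_percent(r.recall))  # 91.7% 87.7%
```

The same stages are available from the shell and compose through files:

```bash
suicidality-nlp synth --n 500 --seed 7 --out corpus.jsonl --gold gold.csv
suicidality-nlp ideation --in corpus.jsonl --out ideation.csv
suicidality-nlp attempt-train --in corpus.jsonl --gold gold.csv --model model.json --seed 7
suicidality-nlp attempt-classify --model model.json --in corpus.jsonl --out attempts.csv
suicidality-nlp filter --in attempts.csv --out filtered.csv --log exclusions.csv
suicidality-nlp evaluate --gold gold.csv --pred filtered.csv --concept attempt --out report.json
suicidality-nlp rollup --in filtered.csv --out rollup.csv
```

All lexicons (negation gazetteers, attempt dictionary, assertion triggers,
exclusion rulebook) are plain-text package data and can be replaced on the
command line or in code to fit local recording practice.

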