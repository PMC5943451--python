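"""Seeded generator of pseudonymised-style psychiatric notes with gold labels.

The source EHR corpus behind this package is access-restricted, so every
stage is exercised against synthetic notes that emulate the mention taxonomy
observed in that kind of data: affirmed and negated suicidal ideation,
affirmed and negated suicide attempts, neutral questionnaire titles and
subheadings, historical mentions, mentions about someone other than the
patient, self-harm explicitly without intent to die, and plain filler.

Documents are assembled one sentence per line from category templates with
lexical jitter (names, drugs, counts, dates drawn from packaged lists); each
suicidality sentence carries its category and a gold binary label
(neutral titles, negated, other-experiencer, self-harm-without-intent and
historical mentions are all ``non_true_event``).  Generation is byte-level
deterministic per seed.

The generator does **not** attempt clinical plausibility beyond the mention
taxonomy — no realistic metadata, layouts or co-morbidity structure.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .corpus_model import (
    NON_TRUE_EVENT,
    TRUE_EVENT,
    ClinicalDocument,
    ConfusionMatrix,
    GoldAnnotation,
    ValidationError,
)

__all__ = [
    "CATEGORIES",
    "SyntheticConfig",
    "ManifestRow",
    "generate",
    "make_gold_fixture",
    "generate_planted_keyword_corpus",
    "gold_by_sentence",
]

CATEGORIES = (
    "affirmed_ideation",
    "negated_ideation",
    "affirmed_attempt",
    "negated_attempt",
    "neutral_title",
    "historical",
    "experiencer_other",
    "self_harm_no_intent",
    "filler",
)

#: Default category mix.  Neutral titles are kept deliberately heavy
#: (>30% of attempt-term mentions) to recreate the questionnaire/subheading
#: burden that motivates the post-processing filters.
DEFAULT_WEIGHTS = {
    "affirmed_ideation": 0.14,
    "negated_ideation": 0.10,
    "affirmed_attempt": 0.16,
    "negated_attempt": 0.08,
    "neutral_title": 0.28,
    "historical": 0.06,
    "experiencer_other": 0.06,
    "self_harm_no_intent": 0.08,
    "filler": 0.04,
}

NAMES = ["Alex", "Sam", "Jordan", "Casey", "Morgan", "Jamie", "Taylor", "Riley", "Robin", "Ash"]
DRUGS = ["paracetamol", "ibuprofen", "codeine", "sertraline", "diazepam", "zopiclone", "citalopram", "mirtazapine"]
DAYS = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday"]

# Each template is (text, gold label, concepts) and must render to exactly
# one sentence under the package splitter (no internal boundaries).
# Affirmed-ideation templates contain a suicid* token before an ideat* token
# and no word from the packaged negation gazetteers, so the rule classifier
# recovers the gold label by construction; negated templates always carry a
# packaged negation term.
TEMPLATES: dict[str, list[tuple[str, str, tuple[str, ...]]]] = {
    "affirmed_ideation": [
        ("{name} reports ongoing suicidal ideation with a plan to take {drug}.", TRUE_EVENT, ("ideation",)),
        ("Ongoing suicidal ideation was discussed at review on {day}.", TRUE_EVENT, ("ideation",)),
        ("{name} describes active suicidal ideation and feelings of hopelessness.", TRUE_EVENT, ("ideation",)),
        ("Mental state examination revealed suicidal ideation with intent.", TRUE_EVENT, ("ideation",)),
        ("Persistent suicidal ideation remains present since {day}.", TRUE_EVENT, ("ideation",)),
    ],
    "negated_ideation": [
        ("{name} denied any suicidal ideation or intent when seen on {day}.", NON_TRUE_EVENT, ("ideation",)),
        ("No suicidal ideation reported at assessment today.", NON_TRUE_EVENT, ("ideation",)),
        ("{name} does not describe suicidal ideation at present.", NON_TRUE_EVENT, ("ideation",)),
        ("Nil suicidal ideation or thoughts of self harm.", NON_TRUE_EVENT, ("ideation",)),
        ("{name} denies current suicidal ideation and is future oriented.", NON_TRUE_EVENT, ("ideation",)),
    ],
    "affirmed_attempt": [
        ("{name} took an overdose of {n} {drug} tablets in a suicide attempt last night.", TRUE_EVENT, ("attempt",)),
        ("{name} made a serious suicide attempt by hanging and was admitted.", TRUE_EVENT, ("attempt",)),
        ("{name} attempted suicide by jumping from a bridge on {day}.", TRUE_EVENT, ("attempt",)),
        ("She attempted to end her life with {n} tablets of {drug}.", TRUE_EVENT, ("attempt",)),
        ("He attempted to kill himself by cutting and required stitches.", TRUE_EVENT, ("attempt",)),
        ("{name} attempted to take her life by walking into traffic on {day}.", TRUE_EVENT, ("attempt",)),
        ("On {day} {name} took a deliberate overdose of {drug} expecting to die.", TRUE_EVENT, ("attempt",)),
    ],
    "negated_attempt": [
        ("{name} denied that the overdose was a suicide attempt.", NON_TRUE_EVENT, ("attempt",)),
        ("{name} has never attempted suicide according to the family.", NON_TRUE_EVENT, ("attempt",)),
        ("She said she would not attempt to take her life while her children were young.", NON_TRUE_EVENT, ("attempt",)),
        ("He states he did not attempt suicide and has no plan to do so.", NON_TRUE_EVENT, ("attempt",)),
    ],
    "neutral_title": [
        ("Suicide attempts/ideation", NON_TRUE_EVENT, ("attempt", "ideation")),
        ("b) Suicide attempts x", NON_TRUE_EVENT, ("attempt",)),
        ("History of previous suicide attempts", NON_TRUE_EVENT, ("attempt",)),
        ("Have you ever attempted suicide?", NON_TRUE_EVENT, ("attempt",)),
        ("Past suicide attempts", NON_TRUE_EVENT, ("attempt",)),
        ("{n}) Suicide attempts", NON_TRUE_EVENT, ("attempt",)),
        ("Suicide attempt history", NON_TRUE_EVENT, ("attempt",)),
    ],
    "historical": [
        ("Many years ago {name} reportedly attempted suicide while living abroad.", NON_TRUE_EVENT, ("attempt",)),
        ("There is a history of attempted suicide before contact with our team.", NON_TRUE_EVENT, ("attempt",)),
        ("Previous suicide attempt by overdose of {drug} noted in old records.", NON_TRUE_EVENT, ("attempt",)),
    ],
    "experiencer_other": [
        ("Her mother attempted suicide when {name} was young.", NON_TRUE_EVENT, ("attempt",)),
        ("His father made a suicide attempt many years before he was born.", NON_TRUE_EVENT, ("attempt",)),
        ("Family history notes that her sister attempted suicide.", NON_TRUE_EVENT, ("attempt",)),
    ],
    "self_harm_no_intent": [
        ("{name} states that the overdose was not a suicide attempt but a way to stop the stress.", NON_TRUE_EVENT, ("attempt",)),
        ("He has claimed cutting brings relief from stress and denied that this was an attempt to kill himself.", NON_TRUE_EVENT, ("attempt",)),
        ("She took {n} tablets of {drug} when feeling sad but not in an attempt to end her life.", NON_TRUE_EVENT, ("attempt",)),
        ("{name} said the self harm was done with a desire to hurt himself and was not a suicide attempt.", NON_TRUE_EVENT, ("attempt",)),
    ],
    "filler": [
        ("Seen at home by the community team on {day}.", "", ()),
        ("Medication {drug} increased to {n} mg daily.", "", ()),
        ("{name} slept well and appetite is improving.", "", ()),
        ("Plan to review in {n} weeks at the clinic.", "", ()),
        ("He was discharged from the ward after a settled weekend.", "", ()),
        ("Mood remains low but stable with ongoing support from the team.", "", ()),
        ("Attended the outpatient clinic accompanied by a support worker.", "", ()),
        ("Engaging well with the care plan agreed last {day}.", "", ()),
    ],
}


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    The document-type mix defaults to 0.55 event / 0.45 correspondence,
    after the roughly 275/225 event-correspondence split of the attempt
    annotation set this generator stands in for.
    """

    n_docs: int = 500
    seed: int = 0
    event_prop: float = 0.55
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    sentences_range: tuple[int, int] = (3, 8)

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValidationError("n_docs must be >= 1")
        unknown = set(self.weights) - set(CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown categories in weights: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("category weights must be >= 0")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"category weights must sum to 1, got {total}")
        lo, hi = self.sentences_range
        if not (1 <= lo <= hi):
            raise ValidationError("sentences_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class ManifestRow:
    """Provenance of one generated suicidality sentence."""

    doc_id: str
    patient_id: str
    sentence_index: int
    category: str
    concept: str
    label: str


def _render(template: str, rng: random.Random) -> str:
    return template.format(
        name=rng.choice(NAMES),
        drug=rng.choice(DRUGS),
        n=rng.randint(2, 9),
        day=rng.choice(DAYS),
    )


def generate(config: SyntheticConfig | None = None):
    """Generate ``(documents, gold_annotations, manifest)`` for the config.

    Gold annotations are keyed ``(doc_id, sentence_index, concept)``; one is
    emitted per concept a suicidality sentence touches (a neutral heading
    like "Suicide attempts/ideation" yields both an attempt and an ideation
    row, each ``non_true_event``).
    """
    if config is None:
        config = SyntheticConfig()
    rng = random.Random(config.seed)
    cats = [c for c in CATEGORIES if config.weights.get(c, 0) > 0]
    cat_weights = [config.weights[c] for c in cats]
    docs: list[ClinicalDocument] = []
    golds: list[GoldAnnotation] = []
    manifest: list[ManifestRow] = []
    n_patients = max(1, config.n_docs // 2)
    for i in range(config.n_docs):
        doc_id = f"doc{i:05d}"
        patient_id = f"p{rng.randrange(n_patients):04d}"
        doc_type = "event" if rng.random() < config.event_prop else "correspondence"
        category = rng.choices(cats, weights=cat_weights, k=1)[0]
        k = rng.randint(*config.sentences_range)
        lines = [_render(rng.choice(TEMPLATES["filler"])[0], rng) for _ in range(k)]
        if category != "filler":
            template, label, concepts = rng.choice(TEMPLATES[category])
            target_index = rng.randrange(k)
            lines[target_index] = _render(template, rng)
            for concept in concepts:
                golds.append(
                    GoldAnnotation(
                        key=(doc_id, target_index, concept), label=label
                    )
                )
                manifest.append(
                    ManifestRow(
                        doc_id=doc_id,
                        patient_id=patient_id,
                        sentence_index=target_index,
                        category=category,
                        concept=concept,
                        label=label,
                    )
                )
        date = f"{rng.randint(2010, 2017)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
        docs.append(
            ClinicalDocument(
                doc_id=doc_id,
                patient_id=patient_id,
                doc_type=doc_type,
                text="\n".join(lines),
                date=date,
            )
        )
    return docs, golds, manifest


MANIFEST_COLUMNS = ["doc_id", "patient_id", "sentence_index", "category", "concept", "label"]


def write_manifest(rows: Sequence[ManifestRow], path) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for row in rows:
            writer.writerow(
                [row.doc_id, row.patient_id, row.sentence_index, row.category, row.concept, row.label]
            )


def read_manifest(path) -> list[ManifestRow]:
    import csv

    rows: list[ManifestRow] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                ManifestRow(
                    doc_id=rec["doc_id"],
                    patient_id=rec["patient_id"],
                    sentence_index=int(rec["sentence_index"]),
                    category=rec["category"],
                    concept=rec["concept"],
                    label=rec["label"],
                )
            )
    return rows


def gold_by_sentence(manifest: Sequence[ManifestRow], concept: str) -> dict[tuple, str]:
    """Gold labels keyed (doc_id, sentence_index) for one concept."""
    return {
        (row.doc_id, row.sentence_index): row.label
        for row in manifest
        if row.concept == concept
    }


def make_gold_fixture(cm: ConfusionMatrix, seed: int = 0):
    """Aligned gold/prediction label mappings whose confusion equals ``cm``."""
    if cm.n == 0:
        raise ValidationError("confusion matrix must contain at least one instance")
    pairs = (
        [(TRUE_EVENT, TRUE_EVENT)] * cm.a
        + [(TRUE_EVENT, NON_TRUE_EVENT)] * cm.b
        + [(NON_TRUE_EVENT, TRUE_EVENT)] * cm.c
        + [(NON_TRUE_EVENT, NON_TRUE_EVENT)] * cm.d
    )
    rng = random.Random(seed)
    rng.shuffle(pairs)
    gold = {f"i{i:06d}": g for i, (g, _p) in enumerate(pairs)}
    pred = {f"i{i:06d}": p for i, (_g, p) in enumerate(pairs)}
    return gold, pred


def generate_planted_keyword_corpus(
    n: int = 500, seed: int = 0, keyword: str = "lorazepam"
):
    """A corpus whose gold label depends only on a planted keyword.

    Every document holds one attempt-term sentence drawn from a shared
    template pool; positives substitute ``keyword`` for the drug slot, so the
    keyword is the only token separating the classes.  Used to verify that
    training recovers planted signal (the keyword's weight should dominate).
    """
    if keyword in DRUGS:
        raise ValidationError("keyword must not collide with the drug list")
    rng = random.Random(seed)
    pool = [
        "{name} reported a suicide attempt involving {drug} on {day}.",
        "Note describes a suicide attempt with {drug} earlier this month.",
        "Admission followed a suicide attempt where {drug} was taken.",
    ]
    docs: list[ClinicalDocument] = []
    labels: list[str] = []
    for i in range(n):
        positive = rng.random() < 0.5
        template = rng.choice(pool)
        text = template.format(
            name=rng.choice(NAMES),
            drug=keyword if positive else rng.choice(DRUGS),
            day=rng.choice(DAYS),
        )
        filler = _render(rng.choice(TEMPLATES["filler"])[0], rng)
        docs.append(
            ClinicalDocument(
                doc_id=f"pk{i:05d}",
                patient_id=f"p{i:05d}",
                doc_type="event",
                text=text + "\n" + filler,
            )
        )
        labels.append(TRUE_EVENT if positive else NON_TRUE_EVENT)
    return docs, labels
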