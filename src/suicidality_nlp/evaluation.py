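"""Evaluation: confusion counts, precision/recall/F1, Cohen's kappa, rollup.

The confusion matrix follows the classifier-rows x gold-columns layout:
``a`` classifier-true & gold-true, ``b`` classifier-false & gold-true,
``c`` classifier-true & gold-false, ``d`` both false.  Precision is
a/(a+c), recall (sensitivity) a/(a+b); both are kept as exact rationals
internally and displayed as one-decimal percentages.  Undefined metrics
(zero denominators) are marked, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping, Sequence

from .corpus_model import (
    TRUE_EVENT,
    ConfusionMatrix,
    MentionClassification,
)

__all__ = [
    "AlignmentError",
    "EvalReport",
    "confusion",
    "precision_recall",
    "format_percent",
    "cohens_kappa",
    "patient_rollup",
]


class AlignmentError(ValueError):
    """Gold and predicted label sets do not share the same keys."""


def confusion(
    gold: Mapping[object, str], predicted: Mapping[object, str]
) -> ConfusionMatrix:
    """Build the 2x2 confusion matrix from aligned key->label mappings."""
    gold_only = sorted(map(repr, set(gold) - set(predicted)))
    pred_only = sorted(map(repr, set(predicted) - set(gold)))
    if gold_only or pred_only:
        raise AlignmentError(
            f"keys only in gold: {gold_only[:5]}; only in predictions: {pred_only[:5]}"
        )
    a = b = c = d = 0
    for key, gold_label in gold.items():
        pred_true = predicted[key] == TRUE_EVENT
        gold_true = gold_label == TRUE_EVENT
        if pred_true and gold_true:
            a += 1
        elif not pred_true and gold_true:
            b += 1
        elif pred_true and not gold_true:
            c += 1
        else:
            d += 1
    return ConfusionMatrix(a=a, b=b, c=c, d=d)


@dataclass
class EvalReport:
    """Precision/recall/F1 over a confusion matrix, exact-rational inside."""

    cm: ConfusionMatrix
    precision: Fraction | None
    recall: Fraction | None
    f1: Fraction | None
    n: int

    def to_dict(self) -> dict:
        def pct(v):
            return None if v is None else format_percent(v)

        return {
            "confusion": {"a": self.cm.a, "b": self.cm.b, "c": self.cm.c, "d": self.cm.d},
            "n": self.n,
            "precision": None if self.precision is None else float(self.precision),
            "recall": None if self.recall is None else float(self.recall),
            "f1": None if self.f1 is None else float(self.f1),
            "precision_pct": pct(self.precision),
            "recall_pct": pct(self.recall),
            "f1_pct": pct(self.f1),
            "undefined": [
                name
                for name, v in (
                    ("precision", self.precision),
                    ("recall", self.recall),
                    ("f1", self.f1),
                )
                if v is None
            ],
        }


def format_percent(value: Fraction | float) -> str:
    """Display convention: one-decimal percentage, e.g. ``'91.7%'``."""
    pct = Decimal(value.numerator) / Decimal(value.denominator) * 100 \
        if isinstance(value, Fraction) else Decimal(str(float(value))) * 100
    return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


def precision_recall(cm: ConfusionMatrix) -> EvalReport:
    """Exact precision a/(a+c), recall a/(a+b) and their harmonic mean."""
    precision = Fraction(cm.a, cm.a + cm.c) if cm.a + cm.c > 0 else None
    recall = Fraction(cm.a, cm.a + cm.b) if cm.a + cm.b > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    return EvalReport(cm=cm, precision=precision, recall=recall, f1=f1, n=cm.n)


def cohens_kappa(
    rater1: Sequence[str], rater2: Sequence[str]
) -> Fraction | None:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Chance agreement p_e uses the product of the two raters' marginals.
    Identical constant ratings give kappa = 1 by convention; any other
    degenerate p_e = 1 case is undefined (None).
    """
    if len(rater1) != len(rater2):
        raise AlignmentError("rater label vectors differ in length")
    n = len(rater1)
    if n == 0:
        raise AlignmentError("need at least one rated instance")
    categories = sorted(set(rater1) | set(rater2))
    p_o = Fraction(sum(1 for x, y in zip(rater1, rater2) if x == y), n)
    p_e = Fraction(0)
    for cat in categories:
        m1 = Fraction(sum(1 for x in rater1 if x == cat), n)
        m2 = Fraction(sum(1 for y in rater2 if y == cat), n)
        p_e += m1 * m2
    if p_e == 1:
        return Fraction(1) if p_o == 1 else None
    return (p_o - p_e) / (1 - p_e)


def patient_rollup(
    classifications: Sequence[MentionClassification],
    patient_ids: Mapping[tuple, str],
) -> dict[str, bool]:
    """Ever-event flag per patient: any surviving true_event mention.

    ``patient_ids`` maps mention keys to patient ids (mention keys do not
    carry the patient, so the caller supplies the mapping — typically
    ``{m.key: m.patient_id for m in mentions}``).
    """
    flags: dict[str, bool] = {}
    for cls in classifications:
        pid = patient_ids[cls.key]
        flags[pid] = flags.get(pid, False) or (cls.label == TRUE_EVENT)
    return flags
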