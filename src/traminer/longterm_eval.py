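"""Long-term diagnosis aggregation and leave-one-person-out evaluation.

A single trajectory is a weak signal of cognitive status; over an observation
window the per-trajectory classifications accumulate into a history ``VTC``
and the long-term hypothesis of diagnosis is simply the most frequent class.
Ties resolve toward the more impaired class (PwD over MCI over healthy) —
clinically conservative — and are flagged.

Cohort evaluation is leave-one-person-out (LOPO): each person is the test
subject of exactly one fold, and their data never enters that fold's training
or validation sets.  Metrics are per-class precision/recall/F1 plus their
unweighted (macro) means, which give equal weight to the minority classes.
A class with no true (resp. predicted) instances has undefined recall
(resp. precision), reported as NaN and excluded from the macro mean rather
than coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .classifier import CLASS_ORDER, ordered_classes

__all__ = [
    "Diagnosis",
    "EvalReport",
    "Fold",
    "long_term_diagnosis",
    "lopo_split",
    "evaluate_labels",
    "evaluate_cohort",
]

#: Severity order used for breaking majority-vote ties (most impaired first).
SEVERITY_ORDER = ("PwD", "MCI", "healthy")


@dataclass(frozen=True)
class Diagnosis:
    """Majority-vote hypothesis of diagnosis over a classification history."""

    label: str
    counts: dict[str, int]
    tie: bool = False


@dataclass(frozen=True)
class Fold:
    """One LOPO fold: trajectory indices for train/validation, one test person."""

    test_person: str
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix and per-class + macro precision/recall/F1."""

    classes: tuple
    confusion: pd.DataFrame  # rows: truth, columns: prediction
    per_class: pd.DataFrame  # index: class; columns precision/recall/f1 (NaN = n/a)
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.to_numpy().tolist(),
            "per_class": {
                str(c): {
                    k: (None if np.isnan(v) else float(v))
                    for k, v in row.items()
                }
                for c, row in self.per_class.iterrows()
            },
            "macro_precision": float(self.macro_precision),
            "macro_recall": float(self.macro_recall),
            "macro_f1": float(self.macro_f1),
        }


def long_term_diagnosis(vtc) -> Diagnosis:
    """Most frequent class of a per-trajectory classification history.

    The order of the history never matters; ties resolve toward the more
    impaired class and set the ``tie`` flag.
    """
    labels = [str(v) for v in vtc]
    if not labels:
        raise ValueError("empty classification history")
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    if set(winners) <= set(SEVERITY_ORDER):
        winners.sort(key=SEVERITY_ORDER.index)
    else:
        winners.sort()
    return Diagnosis(label=winners[0], counts=counts, tie=len(winners) > 1)


def lopo_split(
    trajectory_person,
    person_class: dict[str, str],
    val_fraction: float = 0.1,
    seed: int = 0,
) -> Iterator[Fold]:
    """Leave-one-person-out folds over trajectory indices.

    ``trajectory_person`` maps each trajectory (by position) to its person.
    Each person becomes the test subject of exactly one fold; the remaining
    persons' trajectories are split, per category, into ~10% validation and
    90% training (seeded).  Raises if a class disappears from a training
    fold.
    """
    persons_arr = np.asarray(trajectory_person)
    persons = sorted(person_class)
    if len(persons) < 2:
        raise ValueError("LOPO needs at least 2 persons")
    classes = ordered_classes(list(person_class.values()))
    for k, test_person in enumerate(persons):
        test_idx = np.flatnonzero(persons_arr == test_person)
        rest_idx = np.flatnonzero(persons_arr != test_person)
        rest_y = np.array([person_class[p] for p in persons_arr[rest_idx]])
        present = set(rest_y.tolist())
        missing = [c for c in classes if c not in present]
        if missing:
            raise ValueError(
                f"class {missing[0]!r} has no training data in fold "
                f"(test person {test_person!r})"
            )
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        val_sel: list[int] = []
        for cls in classes:
            cls_idx = rest_idx[rest_y == cls]
            n_val = max(1, int(len(cls_idx) * val_fraction)) if len(cls_idx) > 1 else 0
            val_sel.extend(rng.choice(cls_idx, size=n_val, replace=False).tolist())
        val_idx = np.array(sorted(val_sel), dtype=int)
        train_idx = np.setdiff1d(rest_idx, val_idx)
        train_y = {person_class[p] for p in persons_arr[train_idx]}
        missing = [c for c in classes if c not in train_y]
        if missing:
            raise ValueError(
                f"class {missing[0]!r} vanished from training in fold "
                f"(test person {test_person!r})"
            )
        yield Fold(
            test_person=test_person,
            train_idx=train_idx,
            val_idx=val_idx,
            test_idx=test_idx,
        )


def evaluate_labels(y_true, y_pred, classes=None) -> EvalReport:
    """Per-class and macro precision/recall/F1 from label sequences.

    Undefined entries (no true instances → recall, no predicted instances →
    precision) are NaN and excluded from the macro averages.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    if classes is None:
        classes = ordered_classes(np.concatenate([y_true, y_pred]))
    classes = tuple(classes)
    cm = confusion_matrix(y_true, y_pred, labels=list(classes))
    tp = np.diag(cm).astype(float)
    pred_n = cm.sum(axis=0).astype(float)
    true_n = cm.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_n > 0, tp / pred_n, np.nan)
        recall = np.where(true_n > 0, tp / true_n, np.nan)
    f1 = np.full(len(classes), np.nan)
    for i in range(len(classes)):
        p, r = precision[i], recall[i]
        if np.isnan(p) or np.isnan(r):
            continue
        f1[i] = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1}, index=list(classes)
    )
    return EvalReport(
        classes=classes,
        confusion=pd.DataFrame(cm, index=list(classes), columns=list(classes)),
        per_class=per_class,
        macro_precision=float(np.nanmean(precision)),
        macro_recall=float(np.nanmean(recall)),
        macro_f1=float(np.nanmean(f1)),
    )


def evaluate_cohort(
    predictions: dict[str, "Diagnosis | str"],
    truths: dict[str, str],
    classes=None,
) -> EvalReport:
    """Cohort-level metrics from per-person diagnoses against true classes."""
    if set(predictions) != set(truths):
        raise ValueError("predictions and truths cover different persons")
    persons = sorted(truths)
    y_true = [truths[p] for p in persons]
    y_pred = [
        predictions[p].label if isinstance(predictions[p], Diagnosis) else predictions[p]
        for p in persons
    ]
    if classes is None:
        classes = ordered_classes(list(y_true) + list(y_pred))
    return evaluate_labels(y_true, y_pred, classes)
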