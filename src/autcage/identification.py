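"""Confusion-matrix identity labeling and its quality metrics.

In the home-cage device every trial is attributed to a subject from a
photograph taken at trial start, with a second capture at trial end as a
consistency check.  Here the classifier is abstracted into a row-stochastic
confusion matrix P(label | true subject) over the subjects plus a ``null``
label (captures in which no face is recognizable, e.g. a trial triggered by
accident).  Start and end labels are drawn independently given the true
subject; trials whose two labels disagree are withheld from the training
controller but kept in the log.

Two accuracy metrics mirror the field's usage: per-label precision (correct
labels over all labels emitted for a subject) and per-subject recall
(correct labels over all trials truly performed by the subject).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NULL_LABEL",
    "IdentityModel",
    "LabeledPair",
    "sample_label",
    "consistency_filter",
    "precision_per_label",
    "recall_per_subject",
]

NULL_LABEL = "null"


@dataclass(frozen=True)
class LabeledPair:
    """Identity labels for one trial: the truth and the two captures."""

    true_id: str
    label_start: str
    label_end: str

    @property
    def consistent(self) -> bool:
        return self.label_start == self.label_end


class IdentityModel:
    """Row-stochastic confusion matrix P(label | true subject).

    Rows are true subjects; columns are the same subjects plus the ``null``
    label.  Rows must sum to 1 (within 1e-9) with non-negative entries.
    """

    def __init__(self, subjects: Sequence[str], confusion: np.ndarray,
                 labels: Optional[Sequence[str]] = None):
        self.subjects = list(subjects)
        self.labels = list(labels) if labels is not None else self.subjects + [NULL_LABEL]
        confusion = np.asarray(confusion, dtype=float)
        if confusion.shape != (len(self.subjects), len(self.labels)):
            raise ValueError(
                f"confusion shape {confusion.shape} does not match "
                f"{len(self.subjects)} subjects × {len(self.labels)} labels")
        if (confusion < 0).any():
            raise ValueError("confusion entries must be non-negative")
        if not np.allclose(confusion.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion rows must each sum to 1")
        self.confusion = confusion
        self._row = {s: i for i, s in enumerate(self.subjects)}

    @classmethod
    def identity(cls, subjects: Sequence[str]) -> "IdentityModel":
        """A perfect classifier: every capture labeled with the truth."""
        subjects = list(subjects)
        mat = np.zeros((len(subjects), len(subjects) + 1))
        np.fill_diagonal(mat, 1.0)
        return cls(subjects, mat)

    @classmethod
    def from_csv(cls, path) -> "IdentityModel":
        """Read a confusion matrix CSV (index = true subjects, columns = labels)."""
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float),
                   list(df.columns.astype(str)))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.confusion, index=self.subjects,
                     columns=self.labels).to_csv(path)

    def row(self, true_id: str) -> np.ndarray:
        try:
            return self.confusion[self._row[true_id]]
        except KeyError:
            raise KeyError(f"unknown subject {true_id!r}") from None

    def consistency_probability(self, true_id: str) -> float:
        """P(start and end labels agree | subject) = Σ_label P(label|s)²."""
        p = self.row(true_id)
        return float(np.sum(p * p))


def sample_label(model: IdentityModel, true_id: str,
                 rng: np.random.Generator) -> str:
    """Draw one capture's label from the subject's confusion row."""
    p = model.row(true_id)
    return model.labels[int(rng.choice(len(model.labels), p=p))]


def sample_pair(model: IdentityModel, true_id: str,
                rng: np.random.Generator) -> LabeledPair:
    """Draw the start and end labels independently given the true subject."""
    return LabeledPair(true_id, sample_label(model, true_id, rng),
                       sample_label(model, true_id, rng))


def consistency_filter(pairs: Sequence[LabeledPair]) -> tuple[list[LabeledPair], int]:
    """Split trials into controller-usable pairs and a mismatch count.

    Pairs whose start and end labels differ are excluded from staircase
    updates (both kinds remain in the session log for the analyses).
    """
    usable = [p for p in pairs if p.consistent]
    return usable, len(pairs) - len(usable)


def _per_subject_fraction(num: pd.Series, den: pd.Series,
                          subjects: Sequence[str]) -> pd.Series:
    out = {}
    for s in subjects:
        d = den.get(s, 0)
        if d > 0:
            out[s] = num.get(s, 0) / d
    return pd.Series(out, dtype=float)


def precision_per_label(labels: Sequence[str], truth: Sequence[str],
                        subjects: Optional[Sequence[str]] = None) -> pd.Series:
    """Fraction of a subject's emitted labels that were actually that subject.

    For subject s: #(label == truth == s) / #(label == s).  Subjects that
    never received a label are absent from the result, not reported as 0.
    """
    labels = pd.Series(list(labels), dtype=object)
    truth = pd.Series(list(truth), dtype=object)
    if subjects is None:
        subjects = sorted(set(truth))
    hits = labels[labels == truth].value_counts()
    return _per_subject_fraction(hits, labels.value_counts(), subjects)


def recall_per_subject(labels: Sequence[str], truth: Sequence[str],
                       subjects: Optional[Sequence[str]] = None) -> pd.Series:
    """Fraction of a subject's true trials that were labeled correctly.

    For subject s: #(label == truth == s) / #(truth == s).
    """
    labels = pd.Series(list(labels), dtype=object)
    truth = pd.Series(list(truth), dtype=object)
    if subjects is None:
        subjects = sorted(set(truth))
    hits = labels[labels == truth].value_counts()
    return _per_subject_fraction(hits, truth.value_counts(), subjects)
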