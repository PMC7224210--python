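"""Multi-rater malignancy ratings to binary nodule and patient labels.

A nodule's 1-5 rater scores are averaged and rounded to the nearest integer
(half rounds up). Rounded ratings 1 and 2 become benign (0), 4 and 5 become
malignant (1), and 3 — indeterminate malignancy — is discarded from both
training and scoring, though indeterminate nodules are kept around for
confidence analysis. A patient is malignant if any of their nodules is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd


class MalignancyLabel(Enum):
    BENIGN = 0
    MALIGNANT = 1
    DISCARD = "discard"


@dataclass
class RatingSet:
    """The 1-4 integer ratings (1-5 scale) attached to one nodule."""

    ratings: list[int]
    nodule_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        if not self.ratings:
            raise ValueError("RatingSet requires at least one rating")
        if not 1 <= len(self.ratings) <= 4:
            raise ValueError("a nodule carries between 1 and 4 ratings")
        if any(not (1 <= r <= 5) or int(r) != r for r in self.ratings):
            raise ValueError("ratings must be integers in 1..5")


def aggregate_ratings(rs: RatingSet | Sequence[int]) -> int:
    """Arithmetic mean of the ratings, rounded to the nearest integer (half up)."""
    ratings = rs.ratings if isinstance(rs, RatingSet) else list(rs)
    if not ratings:
        raise ValueError("cannot aggregate an empty rating list")
    mean = sum(ratings) / len(ratings)
    return int(min(5, max(1, math.floor(mean + 0.5))))


def binarize_label(rounded: int) -> MalignancyLabel:
    """Map a rounded 1-5 rating to benign / malignant / discard."""
    if rounded not in (1, 2, 3, 4, 5):
        raise ValueError(f"rounded rating must be in 1..5, got {rounded!r}")
    if rounded in (1, 2):
        return MalignancyLabel.BENIGN
    if rounded in (4, 5):
        return MalignancyLabel.MALIGNANT
    return MalignancyLabel.DISCARD


def label_from_ratings(rs: RatingSet | Sequence[int]) -> MalignancyLabel:
    """Convenience composition: aggregate then binarize."""
    return binarize_label(aggregate_ratings(rs))


def patient_label(nodule_labels: Iterable[int]) -> int:
    """1 iff any nodule is malignant (discarded nodules must be removed first)."""
    labels = list(nodule_labels)
    if not labels:
        raise ValueError("patient_label needs at least one labeled nodule")
    if any(l not in (0, 1) for l in labels):
        raise ValueError("nodule labels must be 0 or 1 (drop DISCARD first)")
    return int(any(l == 1 for l in labels))


def labels_table(rating_sets: Iterable[RatingSet]) -> pd.DataFrame:
    """Per-nodule label table (nodule_id, patient_id, rounded_rating, label).

    ``label`` is 0/1, or the string ``"discard"`` for indeterminate nodules.
    """
    rows = []
    for rs in rating_sets:
        rounded = aggregate_ratings(rs)
        lab = binarize_label(rounded)
        rows.append(
            {
                "nodule_id": rs.nodule_id,
                "patient_id": rs.patient_id,
                "rounded_rating": rounded,
                "label": lab.value,
            }
        )
    return pd.DataFrame(rows, columns=["nodule_id", "patient_id", "rounded_rating", "label"])
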