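"""Mastoiditis label calculus.

Each ear of a mastoid AP view carries an ordinal mastoiditis category:

* 0 — normal, clear mastoid air cells
* 1 — mild, partial haziness of the air cells
* 2 — severe, total haziness with sclerosis
* 3 — postoperative (mastoidectomy) state

Postoperative ears are inherently asymmetric and are excluded from all
symmetry computations; subjects with a category-3 ear are retained in parsed
label tables with an ``excluded`` flag so exclusion counts stay auditable.

The bilateral *symmetry grade* is the absolute difference of the two ears'
categories (restricted to 0-2), giving grades 0 (concordant), 1 (one-stage
difference) and 2 (normal vs severe).

For binary diagnostic metrics each ear is dichotomized: negative if normal,
positive if mild or severe.  The continuous positive-class score used for ROC
analysis is ``1 - p(normal)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EarCategory",
    "SymmetryGrade",
    "BilateralLabel",
    "ExclusionError",
    "LabelParseError",
    "symmetry_grade",
    "dichotomize_label",
    "dichotomize_prediction",
    "read_label_table",
]

#: categories that participate in symmetry evaluation
SYMMETRY_CATEGORIES = (0, 1, 2)
POSTOPERATIVE = 3


class ExclusionError(ValueError):
    """Raised when a postoperative (category 3) ear enters a computation
    defined only for categories 0-2."""


class LabelParseError(ValueError):
    """Raised when a label table row cannot be parsed; names the row."""


class EarCategory(enum.IntEnum):
    NORMAL = 0
    MILD = 1
    SEVERE = 2
    POSTOPERATIVE = 3


class SymmetryGrade(enum.IntEnum):
    CONCORDANT = 0
    ONE_STAGE = 1
    TWO_STAGE = 2


def _check_category(value: int, *, context: str = "category") -> int:
    value = int(value)
    if value == POSTOPERATIVE:
        raise ExclusionError(
            f"{context} 3 (postoperative) is excluded from symmetry evaluation"
        )
    if value not in SYMMETRY_CATEGORIES:
        raise ValueError(f"{context} must be in {{0,1,2,3}}, got {value}")
    return value


def symmetry_grade(right: int, left: int) -> SymmetryGrade:
    """Symmetry grade of a bilateral pair: ``|right - left|``.

    Symmetric in its arguments.  Raises :class:`ExclusionError` if either
    side is postoperative (category 3).
    """
    r = _check_category(right, context="right category")
    l = _check_category(left, context="left category")
    return SymmetryGrade(abs(r - l))


def dichotomize_label(cat: int) -> int:
    """Binary outcome of a true category: 0 (negative) if normal, 1
    (positive) if mild or severe."""
    c = _check_category(cat)
    return int(c > 0)


def dichotomize_prediction(probs) -> tuple[int, float]:
    """Dichotomize a 3-class probability vector.

    Returns ``(outcome, score)`` where outcome is 1 (positive) unless the
    normal category holds the strictly highest probability, and the
    positive-class score is ``p(mild) + p(severe) = 1 - p(normal)``.

    An argmax tie between normal and an abnormal category is resolved
    toward positive (screening favours sensitivity).
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"expected a 3-vector of category probabilities, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError("category probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"category probabilities must sum to 1, got {p.sum():.8f}")
    score = float(p[1] + p[2])
    outcome = 0 if p[0] > max(p[1], p[2]) else 1
    return outcome, score


@dataclass(frozen=True)
class BilateralLabel:
    """Consensus label of one subject's two ears with the derived grade."""

    subject_id: str
    right: EarCategory
    left: EarCategory
    excluded: bool = field(default=False)

    def __post_init__(self) -> None:
        if int(self.right) not in (0, 1, 2, 3) or int(self.left) not in (0, 1, 2, 3):
            raise ValueError("ear categories must be in {0,1,2,3}")
        has_postop = POSTOPERATIVE in (int(self.right), int(self.left))
        if has_postop and not self.excluded:
            raise ValueError("labels with a postoperative ear must carry excluded=True")

    @property
    def grade(self) -> SymmetryGrade:
        if self.excluded:
            raise ExclusionError(
                f"subject {self.subject_id!r} is excluded; no symmetry grade"
            )
        return symmetry_grade(int(self.right), int(self.left))


def read_label_table(path: str | Path) -> list[BilateralLabel]:
    """Read a label CSV with columns ``subject_id,right_category,left_category``.

    Rows with a postoperative ear are flagged ``excluded`` rather than
    dropped.  Malformed rows raise :class:`LabelParseError` naming the row.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = ["subject_id", "right_category", "left_category"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LabelParseError(f"label table {path} is missing columns {missing}")
    labels: list[BilateralLabel] = []
    for i, row in df.iterrows():
        try:
            r = int(row["right_category"])
            l = int(row["left_category"])
        except (TypeError, ValueError) as exc:
            raise LabelParseError(
                f"row {i} (subject {row['subject_id']!r}): non-integer category"
            ) from exc
        if r not in (0, 1, 2, 3) or l not in (0, 1, 2, 3):
            raise LabelParseError(
                f"row {i} (subject {row['subject_id']!r}): category out of range 0-3 "
                f"(right={r}, left={l})"
            )
        excluded = POSTOPERATIVE in (r, l)
        labels.append(
            BilateralLabel(
                subject_id=str(row["subject_id"]),
                right=EarCategory(r),
                left=EarCategory(l),
                excluded=excluded,
            )
        )
    return labels
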