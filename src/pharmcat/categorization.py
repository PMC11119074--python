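"""Complexity categories: tertile-derived cut-offs and ordinal assignment.

Raw complexity totals are hard to act on; pharmacy services negotiate
grants per ordinal category instead.  Cut-offs between low, medium and
high complexity are taken from the empirical score distribution at its
first and third tertiles (33.3% and 66.7%).  We make the tertile rule
precise as order statistics: with the n scores sorted ascending, the low
category's inclusive upper bound is the score at rank ceil(n/3) and the
medium category's at rank ceil(2n/3).  Both boundaries are then observed
scores, the rule is deterministic under ties, and for integer scores the
categories have integer edges.

The boundary values published for the original 120-score development
cohort (low <= 19 < medium <= 25 < high) are packaged as
:func:`study_cutoffs`; they are reference constants, not re-derived.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import DegenerateDistributionError, InsufficientDataError

__all__ = ["ComplexityCategory", "CutoffSet", "derive_cutoffs", "study_cutoffs", "categorize"]


class ComplexityCategory(enum.IntEnum):
    """Ordinal trial-complexity category: low < medium < high."""

    low = 0
    medium = 1
    high = 2

    def __str__(self) -> str:  # CSV/JSON-friendly
        return self.name


@dataclass(frozen=True)
class CutoffSet:
    """Inclusive upper bounds of the low and medium categories."""

    low_max: int
    med_max: int

    def __post_init__(self) -> None:
        if not self.low_max < self.med_max:
            raise ValueError(f"low_max ({self.low_max}) must be < med_max ({self.med_max})")


def derive_cutoffs(scores: Sequence[int] | Iterable[int]) -> CutoffSet:
    """Derive category cut-offs from an empirical score distribution.

    The boundaries are the order statistics at ranks ceil(n/3) and
    ceil(2n/3) of the sorted scores — the first and third tertiles.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 scores are supplied.
    DegenerateDistributionError
        If the two boundaries coincide (distribution too concentrated to
        support three categories).
    """
    s = sorted(scores)
    n = len(s)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 scores to derive tertile cut-offs, got {n}")
    low_max = s[-(-n // 3) - 1]        # rank ceil(n/3), 1-based
    med_max = s[-(-2 * n // 3) - 1]    # rank ceil(2n/3), 1-based
    if low_max >= med_max:
        raise DegenerateDistributionError(
            f"tertile boundaries coincide (low_max = med_max = {low_max}); "
            "distribution too concentrated to split into three categories"
        )
    return CutoffSet(low_max=low_max, med_max=med_max)


def study_cutoffs() -> CutoffSet:
    """The published reference cut-offs from the development cohort.

    Low complexity up to 19 points, medium 20–25, high 26 and above.
    """
    return CutoffSet(low_max=19, med_max=25)


def categorize(total: int, cutoffs: CutoffSet | None = None) -> ComplexityCategory:
    """Map a total score to its ordinal complexity category.

    ``low`` if total <= low_max, ``medium`` if low_max < total <= med_max,
    ``high`` otherwise.  Totals below the instrument minimum are accepted
    (they are a validation concern, not a categorization one), but negative
    totals are a domain error.
    """
    c = cutoffs or study_cutoffs()
    if total < 0:
        raise ValueError(f"total score must be non-negative, got {total}")
    if total <= c.low_max:
        return ComplexityCategory.low
    if total <= c.med_max:
        return ComplexityCategory.medium
    return ComplexityCategory.high
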