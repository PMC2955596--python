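"""Weighted dimension scores, categories and mobility profile groups.

Each of the three dimensions (modulators, potential mobility, effective
mobility) is summarised by the number of successful dichotomous items out
of the items actually assessed, rescaled to a common 0-4 range:

    weighted = 4 * n_success / n_assessed

so that participants whose batteries differ in length stay comparable.
The unrounded weighted value maps onto three categories — low (< 1),
moderate (1 to < 3), high (3 to 4) — and the triplet of categories maps
onto profile groups A-D, with the effective-mobility category deciding
first: high effective mobility splits into A (jointly high potential and
positive modulators) versus B, moderate effective mobility is C, and low
effective mobility is D.

Weighted values are exact :class:`fractions.Fraction` internally; rounding
(half-up, two decimals) happens only when a score is displayed.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import MeasurementError, UndefinedScoreError
from .registry import BinaryOutcome, Dimension

__all__ = [
    "Category",
    "Group",
    "DimensionScore",
    "ParticipantProfile",
    "CohortSummary",
    "count_outcomes",
    "weighted_score",
    "format_weighted",
    "categorize",
    "score_dimension",
    "build_profile",
    "assign_group",
    "summarize_cohort",
]


class Category(str, enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class Group(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"


Number = Union[int, float, Fraction]


def count_outcomes(outcomes: Sequence[BinaryOutcome]) -> tuple[int, int]:
    """(n_success, n_assessed) over one participant-dimension outcome set.

    Missing outcomes are not assessed; an empty input returns (0, 0).
    """
    if outcomes:
        pids = {o.participant_id for o in outcomes}
        dims = {o.dimension for o in outcomes}
        if len(pids) > 1 or len(dims) > 1:
            raise MeasurementError(
                "count_outcomes needs outcomes from a single participant and "
                f"dimension, got participants={sorted(pids)} "
                f"dimensions={sorted(d.value for d in dims)}"
            )
    assessed = [o for o in outcomes if not o.is_missing]
    return sum(o.value for o in assessed), len(assessed)


def weighted_score(n_success: int, n_assessed: int) -> Fraction:
    """Exact weighted composite 4 * n_success / n_assessed on the 0-4 scale."""
    if n_assessed < 1:
        raise UndefinedScoreError("no assessed items: weighted score undefined")
    if not 0 <= n_success <= n_assessed:
        raise MeasurementError(
            f"n_success={n_success} outside [0, n_assessed={n_assessed}]"
        )
    return Fraction(4 * n_success, n_assessed)


def format_weighted(value: Number) -> str:
    """Two-decimal display string, rounding half-up (1/3 of 4 -> '1.33')."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    return str(dec.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def categorize(value: Number) -> Category:
    """Map an unrounded weighted value to low (< 1), moderate (1 to < 3) or
    high (3 to 4)."""
    if not 0 <= value <= 4:
        raise MeasurementError(f"weighted value {value} outside [0, 4]")
    if value < 1:
        return Category.LOW
    if value < 3:
        return Category.MODERATE
    return Category.HIGH


@dataclass(frozen=True)
class DimensionScore:
    """One dimension's composite: counts, exact weighted value, category."""

    dimension: Dimension
    n_success: int
    n_assessed: int
    weighted: Fraction
    category: Category

    @property
    def display(self) -> str:
        return format_weighted(self.weighted)

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension.value,
            "n_success": self.n_success,
            "n_assessed": self.n_assessed,
            "weighted_fraction": f"{self.weighted.numerator}/{self.weighted.denominator}",
            "weighted_display": self.display,
            "category": self.category.value,
        }


def score_dimension(outcomes: Sequence[BinaryOutcome]) -> DimensionScore:
    """Count, weight out of four and categorize one dimension's outcomes."""
    if not outcomes:
        raise UndefinedScoreError("no outcomes supplied for dimension")
    n_success, n_assessed = count_outcomes(outcomes)
    if n_assessed == 0:
        raise UndefinedScoreError(
            f"{outcomes[0].dimension.value}: all items missing, score undefined"
        )
    weighted = weighted_score(n_success, n_assessed)
    return DimensionScore(
        dimension=outcomes[0].dimension,
        n_success=n_success,
        n_assessed=n_assessed,
        weighted=weighted,
        category=categorize(weighted),
    )


def assign_group(
    effective: Category, potential: Category, modulators: Category
) -> Group:
    """Profile group from the three categories, effective mobility first.

    A: high effective with jointly high potential and positive modulators;
    B: high effective otherwise; C: moderate effective; D: low effective.
    Total and deterministic over all 27 category triplets.
    """
    if effective is Category.HIGH:
        if potential is Category.HIGH and modulators is Category.HIGH:
            return Group.A
        return Group.B
    if effective is Category.MODERATE:
        return Group.C
    return Group.D


@dataclass(frozen=True)
class ParticipantProfile:
    """Three dimension scores plus the assigned profile group.

    ``group`` is None when the profile is incomplete (some dimension had no
    assessed item); such profiles are excluded from cohort grouping with
    ``incomplete_reason`` recording why.
    """

    participant_id: str
    modulator_score: Optional[DimensionScore]
    potential_score: Optional[DimensionScore]
    effective_score: Optional[DimensionScore]
    group: Optional[Group]
    incomplete_reason: Optional[str] = None

    @property
    def is_complete(self) -> bool:
        return self.group is not None

    def score(self, dimension: Dimension) -> Optional[DimensionScore]:
        return {
            Dimension.MODULATOR: self.modulator_score,
            Dimension.POTENTIAL: self.potential_score,
            Dimension.EFFECTIVE: self.effective_score,
        }[dimension]

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "scores": {
                d.value: (s.to_dict() if s is not None else None)
                for d in Dimension
                for s in [self.score(d)]
            },
            "group": self.group.value if self.group else None,
            "incomplete_reason": self.incomplete_reason,
        }


def build_profile(
    participant_id: str, outcomes: Sequence[BinaryOutcome]
) -> ParticipantProfile:
    """Score all three dimensions for one participant and assign a group.

    ``outcomes`` holds the participant's dichotomized items across all
    dimensions (alternates already resolved).  A dimension in which every
    item is missing leaves the profile incomplete rather than imputed: the
    weighting rescales partial batteries, never absent ones.
    """
    scores: dict[Dimension, Optional[DimensionScore]] = {}
    missing_dims: list[str] = []
    for dim in Dimension:
        dim_outcomes = [o for o in outcomes if o.dimension == dim]
        try:
            scores[dim] = score_dimension(dim_outcomes)
        except UndefinedScoreError:
            scores[dim] = None
            missing_dims.append(dim.value)

    if missing_dims:
        return ParticipantProfile(
            participant_id=participant_id,
            modulator_score=scores[Dimension.MODULATOR],
            potential_score=scores[Dimension.POTENTIAL],
            effective_score=scores[Dimension.EFFECTIVE],
            group=None,
            incomplete_reason=f"no assessed items in: {', '.join(missing_dims)}",
        )
    return ParticipantProfile(
        participant_id=participant_id,
        modulator_score=scores[Dimension.MODULATOR],
        potential_score=scores[Dimension.POTENTIAL],
        effective_score=scores[Dimension.EFFECTIVE],
        group=assign_group(
            scores[Dimension.EFFECTIVE].category,
            scores[Dimension.POTENTIAL].category,
            scores[Dimension.MODULATOR].category,
        ),
    )


@dataclass
class CohortSummary:
    """Cohort-level roll-up: category counts per dimension, group sizes and
    the long-format table (participant, dimension, weighted, category)
    behind the per-participant score chart."""

    category_counts: dict[Dimension, Counter]
    group_sizes: dict[Group, int]
    long_table: pd.DataFrame = field(repr=False)
    n_profiled: int = 0

    def to_dict(self) -> dict:
        return {
            "n_profiled": self.n_profiled,
            "category_counts": {
                d.value: {c.value: self.category_counts[d].get(c, 0) for c in Category}
                for d in Dimension
            },
            "group_sizes": {g.value: self.group_sizes.get(g, 0) for g in Group},
        }


def summarize_cohort(profiles: Iterable[ParticipantProfile]) -> CohortSummary:
    """Summarise complete profiles; incomplete ones are skipped."""
    complete = [p for p in profiles if p.is_complete]
    if not complete:
        raise UndefinedScoreError("no complete profiles to summarise")
    category_counts: dict[Dimension, Counter] = {d: Counter() for d in Dimension}
    group_sizes: dict[Group, int] = {g: 0 for g in Group}
    rows = []
    for p in complete:
        group_sizes[p.group] += 1
        for dim in Dimension:
            s = p.score(dim)
            category_counts[dim][s.category] += 1
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "dimension": dim.value,
                    "weighted": float(s.weighted),
                    "weighted_display": s.display,
                    "category": s.category.value,
                    "group": p.group.value,
                }
            )
    long_table = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "dimension",
            "weighted",
            "weighted_display",
            "category",
            "group",
        ],
    )
    return CohortSummary(
        category_counts=category_counts,
        group_sizes=group_sizes,
        long_table=long_table,
        n_profiled=len(complete),
    )
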