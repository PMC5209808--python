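"""Weighted totals for score sheets: criterion totals, overall
prioritisation scores, and integer gap-area scores.

A criterion's weighted total is simply ``coefficient × Σ raw scores``
over its sub-criteria; the prioritisation overall score is the sum over
the six criteria and is reported unrounded. Gap-area totals are rounded
half away from zero to an integer, and a positive value flags a
research gap in that area (diagnostics, vaccines or pharmaceuticals).

Availability override
---------------------
Each gap area's first sub-criterion records product availability. When
a sheet flags an area as ``none`` (no product exists, not even in
development), the area receives a fixed maximum instead of its scored
total. Two interpretations are supported:

``raw_cap`` (default)
    the area's *raw score sum* is set to 20 before weighting — the most
    literal reading of "a maximum raw score of 20 for the whole
    criterion" (yielding 83 for diagnostics, 91 for the 11-level
    areas);
``display_cap``
    the *final* integer is set to a configured ceiling (default 40),
    matching the apparent ceiling seen in published gap tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

from ._rounding import round_half_away
from .model_core import CriterionSpec, ModelSpec

__all__ = [
    "CATEGORIES",
    "AVAILABILITY_FLAGS",
    "GAP_AREAS",
    "ScoreSheet",
    "DiseaseTotal",
    "GapTotals",
    "SheetValidationError",
    "validate_sheet",
    "criterion_total",
    "disease_total",
    "gap_totals",
    "RAW_CAP_SCORE",
    "DISPLAY_CAP_DEFAULT",
]

CATEGORIES = ("epizootic", "food_producing_complex", "zoonotic")
AVAILABILITY_FLAGS = ("available", "in_development", "none")

#: Canonical short names for the three gap areas, in model order.
GAP_AREAS = {
    "Diagnostic tools": "diagnostics",
    "Vaccination tools": "vaccines",
    "Pharmaceutical tools": "pharmaceuticals",
}

RAW_CAP_SCORE = 20  # raw-sum ceiling applied when no product is available
DISPLAY_CAP_DEFAULT = 40

AvailabilityMode = Literal["raw_cap", "display_cap"]


class SheetValidationError(ValueError):
    """A score sheet does not conform to its governing model."""


@dataclass(frozen=True)
class ScoreSheet:
    """One disease's integer scores for every sub-criterion of a model.

    ``scores`` maps ``(criterion name, sub-criterion name)`` to the raw
    integer score. Gap sheets additionally carry ``availability_flags``
    per area. ``notes`` holds free-text remarks (e.g. gaps identified by
    the expert group) and plays no part in any computation.
    """

    disease_id: str
    disease_name: str
    category: str
    scores: Mapping[tuple[str, str], int]
    availability_flags: Mapping[str, str] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SheetValidationError(
                f"{self.disease_id}: unknown category {self.category!r};"
                f" expected one of {CATEGORIES}"
            )
        object.__setattr__(self, "scores", dict(self.scores))
        object.__setattr__(self, "availability_flags", dict(self.availability_flags))

    def score(self, criterion: str, sub_criterion: str) -> int:
        return self.scores[(criterion, sub_criterion)]


@dataclass(frozen=True)
class DiseaseTotal:
    """Weighted per-criterion totals and their unrounded sum."""

    disease_id: str
    per_criterion: Mapping[str, float]
    overall: float
    disease_name: str = ""
    category: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_criterion", dict(self.per_criterion))


@dataclass(frozen=True)
class GapTotals:
    """Integer gap scores per area; positive means a research gap."""

    disease_id: str
    diagnostics: int
    vaccines: int
    pharmaceuticals: int
    disease_name: str = ""
    category: str | None = None

    @property
    def is_gap(self) -> dict[str, bool]:
        return {
            "diagnostics": self.diagnostics > 0,
            "vaccines": self.vaccines > 0,
            "pharmaceuticals": self.pharmaceuticals > 0,
        }

    def area(self, name: str) -> int:
        try:
            return {
                "diagnostics": self.diagnostics,
                "vaccines": self.vaccines,
                "pharmaceuticals": self.pharmaceuticals,
            }[name]
        except KeyError:
            raise ValueError(f"unknown gap area {name!r}") from None


def validate_sheet(sheet: ScoreSheet, model: ModelSpec) -> None:
    """Raise :class:`SheetValidationError` unless the sheet is complete
    and every score is on its criterion's scale.

    Incomplete sheets are rejected outright — there is no imputation of
    missing sub-criterion scores.
    """
    problems: list[str] = []
    expected = set()
    for crit in model.criteria:
        for sub in crit.sub_criteria:
            key = (crit.name, sub.name)
            expected.add(key)
            if key not in sheet.scores:
                problems.append(f"missing score for {crit.name!r} / {sub.name!r}")
                continue
            value = sheet.scores[key]
            if not isinstance(value, int) or isinstance(value, bool):
                problems.append(
                    f"score for {crit.name!r} / {sub.name!r} is not an integer:"
                    f" {value!r}"
                )
            elif value not in crit.scale:
                problems.append(
                    f"score {value} for {crit.name!r} / {sub.name!r} outside scale"
                    f" {crit.scale.allowed_values}"
                )
    for key in sorted(set(sheet.scores) - expected):
        problems.append(f"unexpected score entry {key!r}")
    if model.model_kind == "gap":
        for area, flag in sheet.availability_flags.items():
            if area not in model.criterion_names():
                problems.append(f"availability flag for unknown area {area!r}")
            if flag not in AVAILABILITY_FLAGS:
                problems.append(
                    f"unknown availability flag {flag!r} for {area!r};"
                    f" expected one of {AVAILABILITY_FLAGS}"
                )
    if problems:
        raise SheetValidationError(
            f"sheet {sheet.disease_id!r} invalid: " + "; ".join(problems)
        )


def criterion_total(sheet: ScoreSheet, criterion: CriterionSpec) -> float:
    """Weighted total ``coefficient × Σ raw scores`` for one criterion,
    unrounded. The maximum attainable value is 100 for every criterion
    (the normalisation guarantee)."""
    total = 0
    for sub in criterion.sub_criteria:
        key = (criterion.name, sub.name)
        if key not in sheet.scores:
            raise SheetValidationError(
                f"sheet {sheet.disease_id!r}: missing score for"
                f" {criterion.name!r} / {sub.name!r}"
            )
        value = sheet.scores[key]
        if value not in criterion.scale:
            raise SheetValidationError(
                f"sheet {sheet.disease_id!r}: score {value} for {criterion.name!r} /"
                f" {sub.name!r} outside scale {criterion.scale.allowed_values}"
            )
        total += value
    return criterion.coefficient * total


def disease_total(sheet: ScoreSheet, model: ModelSpec) -> DiseaseTotal:
    """Overall prioritisation score: the unrounded sum of the six
    weighted criterion totals.

    With the default model the first five criteria each contribute
    0..100 and control tools −100..+100 (missing tools push a disease
    up the list), so the overall score lies in [−100, 600].
    """
    if model.model_kind != "prioritisation":
        raise ValueError("disease_total requires a prioritisation model")
    per = {c.name: criterion_total(sheet, c) for c in model.criteria}
    return DiseaseTotal(
        disease_id=sheet.disease_id,
        per_criterion=per,
        overall=sum(per.values()),
        disease_name=sheet.disease_name,
        category=sheet.category,
    )


def gap_totals(
    sheet: ScoreSheet,
    model: ModelSpec,
    availability_mode: AvailabilityMode = "raw_cap",
    display_cap: int = DISPLAY_CAP_DEFAULT,
) -> GapTotals:
    """Integer gap scores for the three control-tool areas.

    Each area's weighted total is rounded half away from zero. An area
    flagged ``none`` (no product available, not even in development) is
    overridden to a fixed maximum per ``availability_mode`` — see the
    module docstring.
    """
    if model.model_kind != "gap":
        raise ValueError("gap_totals requires a gap-analysis model")
    if availability_mode not in ("raw_cap", "display_cap"):
        raise ValueError(f"unknown availability_mode {availability_mode!r}")
    for area, flag in sheet.availability_flags.items():
        if flag not in AVAILABILITY_FLAGS:
            raise SheetValidationError(
                f"sheet {sheet.disease_id!r}: unknown availability flag {flag!r}"
                f" for {area!r}"
            )
    values: dict[str, int] = {}
    for crit in model.criteria:
        raw_sum = sum(
            _checked_score(sheet, crit, sub.name) for sub in crit.sub_criteria
        )
        flag = sheet.availability_flags.get(crit.name, "available")
        if flag == "none":
            if availability_mode == "raw_cap":
                value = round_half_away(crit.coefficient * RAW_CAP_SCORE)
            else:
                value = float(display_cap)
        else:
            value = round_half_away(crit.coefficient * raw_sum)
        values[GAP_AREAS.get(crit.name, crit.name)] = int(value)
    return GapTotals(
        disease_id=sheet.disease_id,
        diagnostics=values["diagnostics"],
        vaccines=values["vaccines"],
        pharmaceuticals=values["pharmaceuticals"],
        disease_name=sheet.disease_name,
        category=sheet.category,
    )


def _checked_score(sheet: ScoreSheet, crit: CriterionSpec, sub_name: str) -> int:
    key = (crit.name, sub_name)
    if key not in sheet.scores:
        raise SheetValidationError(
            f"sheet {sheet.disease_id!r}: missing score for {crit.name!r} /"
            f" {sub_name!r}"
        )
    value = sheet.scores[key]
    if value not in crit.scale:
        raise SheetValidationError(
            f"sheet {sheet.disease_id!r}: score {value} for {crit.name!r} /"
            f" {sub_name!r} outside scale {crit.scale.allowed_values}"
        )
    return value
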