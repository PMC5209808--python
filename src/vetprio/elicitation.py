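"""Aggregation of expert-panel scores into per-disease consensus sheets.

Each disease is scored by its own expert panel (on average about seven
experts), ideally spanning four areas of expertise: laboratory and
diagnostic work, epidemiology, industry, and economics/trade. The panel
produces one consensus score per sub-criterion; where the experts'
scores spread too far apart, the disagreement itself is recorded as a
knowledge gap (a :class:`DissentRecord`) rather than hidden behind the
aggregate.

The consensus statistic is the median: robust to a single outlier
expert and exact for unanimous panels. Even-panel halves round away
from zero — toward the more extreme (higher-priority or deeper-gap)
value — and the result is clamped to the criterion's scale.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence

from ._rounding import round_half_away
from .model_core import ModelSpec
from .scoring import ScoreSheet, SheetValidationError, validate_sheet

__all__ = [
    "EXPERT_ROLES",
    "REQUIRED_ROLES",
    "PanelScores",
    "DissentRecord",
    "aggregate_panel",
    "panel_coverage_summary",
]

EXPERT_ROLES = ("diagnostic", "epidemiology", "industry", "economics", "other")

#: The four areas of expertise a well-composed panel covers.
REQUIRED_ROLES = frozenset({"diagnostic", "epidemiology", "industry", "economics"})


@dataclass(frozen=True)
class Expert:
    expert_id: str
    role: str
    sheet: ScoreSheet

    def __post_init__(self) -> None:
        if self.role not in EXPERT_ROLES:
            raise ValueError(
                f"unknown expert role {self.role!r}; expected one of {EXPERT_ROLES}"
            )


@dataclass(frozen=True)
class PanelScores:
    """All experts' score sheets for one disease."""

    disease_id: str
    experts: tuple[Expert, ...]

    def __post_init__(self) -> None:
        experts = tuple(self.experts)
        if not experts:
            raise ValueError(f"panel for {self.disease_id!r} has no experts")
        ids = [e.expert_id for e in experts]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate expert_ids in panel {self.disease_id!r}")
        for e in experts:
            if e.sheet.disease_id != self.disease_id:
                raise SheetValidationError(
                    f"panel {self.disease_id!r} contains a sheet for"
                    f" {e.sheet.disease_id!r}"
                )
        object.__setattr__(self, "experts", experts)

    @property
    def size(self) -> int:
        return len(self.experts)

    @property
    def minimum_coverage_met(self) -> bool:
        """True iff at least four experts together span the four
        required areas of expertise."""
        roles = {e.role for e in self.experts}
        return self.size >= 4 and REQUIRED_ROLES <= roles


@dataclass(frozen=True)
class DissentRecord:
    """A sub-criterion on which the panel spread exceeded the dissent
    threshold — recorded as a gap in knowledge."""

    disease_id: str
    criterion: str
    sub_criterion: str
    expert_scores: tuple[int, ...]  # sorted multiset
    consensus_value: int

    @property
    def range(self) -> int:
        return max(self.expert_scores) - min(self.expert_scores)


def _consensus(scores: Sequence[int], scale_values: tuple[int, ...]) -> int:
    med = statistics.median(scores)
    value = int(round_half_away(med))
    # clamp to scale (only reachable if the scale is sparse)
    lo, hi = scale_values[0], scale_values[-1]
    value = max(lo, min(hi, value))
    if value not in scale_values:
        value = min(scale_values, key=lambda v: (abs(v - value), -v))
    return value


def aggregate_panel(
    panel: PanelScores,
    model: ModelSpec,
    dissent_threshold: int = 1,
) -> tuple[ScoreSheet, list[DissentRecord]]:
    """Aggregate a panel to a consensus sheet plus dissent records.

    For every sub-criterion the consensus score is the median of the
    expert scores (halves away from zero, clamped to the scale). A
    :class:`DissentRecord` is emitted whenever the expert score range
    (max − min) exceeds ``dissent_threshold``; with the default of 1,
    adjacent scores count as agreement and a knowledge gap is flagged
    only for a spread of two or more.

    The result is independent of expert order, and a consensus value
    always lies within [min, max] of the expert scores.
    """
    if dissent_threshold < 0:
        raise ValueError("dissent_threshold must be >= 0")
    for expert in panel.experts:
        validate_sheet(expert.sheet, model)

    first = panel.experts[0].sheet
    consensus: dict[tuple[str, str], int] = {}
    dissent: list[DissentRecord] = []
    for crit in model.criteria:
        for sub in crit.sub_criteria:
            key = (crit.name, sub.name)
            scores = sorted(e.sheet.scores[key] for e in panel.experts)
            value = _consensus(scores, crit.scale.allowed_values)
            consensus[key] = value
            if scores[-1] - scores[0] > dissent_threshold:
                dissent.append(
                    DissentRecord(
                        disease_id=panel.disease_id,
                        criterion=crit.name,
                        sub_criterion=sub.name,
                        expert_scores=tuple(scores),
                        consensus_value=value,
                    )
                )

    # availability flags: majority vote, ties resolved to the more
    # pessimistic flag (none > in_development > available)
    flags: dict[str, str] = {}
    if model.model_kind == "gap":
        severity = {"available": 0, "in_development": 1, "none": 2}
        for crit in model.criteria:
            votes = [
                e.sheet.availability_flags.get(crit.name, "available")
                for e in panel.experts
            ]
            flags[crit.name] = max(
                set(votes), key=lambda f: (votes.count(f), severity[f])
            )

    sheet = ScoreSheet(
        disease_id=panel.disease_id,
        disease_name=first.disease_name,
        category=first.category,
        scores=consensus,
        availability_flags=flags,
        notes=first.notes,
    )
    return sheet, dissent


def panel_coverage_summary(
    panels: Sequence[PanelScores],
) -> tuple[int, int, int, float]:
    """Counts of panels meeting the four-role minimum.

    Returns ``(n_panels, n_meeting_minimum, percent_meeting_minimum,
    mean_panel_size)``; the percentage is rounded half away from zero
    to an integer.
    """
    if not panels:
        raise ValueError("panel_coverage_summary requires at least one panel")
    n = len(panels)
    n_meeting = sum(1 for p in panels if p.minimum_coverage_met)
    percent = int(round_half_away(100.0 * n_meeting / n))
    mean_size = sum(p.size for p in panels) / n
    return n, n_meeting, percent, mean_size
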