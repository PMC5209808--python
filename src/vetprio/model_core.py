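"""Scoring-model definitions for disease prioritisation and gap analysis.

A scoring model is a closed weighted system: each *criterion* groups a
handful of scored items (its *levels*, or sub-criteria), every level is
scored on a small integer scale, and a per-level weighting coefficient

    W = 100 / (X * I)

(X = maximum score of a level, I = number of levels) normalises every
criterion's maximum weighted total to exactly 100, so all criteria carry
the same weight in the overall score.

Two concrete models ship with the package:

* the six-criterion prioritisation model (disease knowledge; impact on
  animal health and welfare; on public health; on wider society; on
  trade; control tools) — first five criteria scored 0..4, control tools
  scored +2..−2 so that missing tools *raise* a disease's priority;
* the three-area gap-analysis model (diagnostic, vaccination and
  pharmaceutical tools), all scored +2 (important gap) .. −2 (current
  tools appropriate), where a positive weighted total flags a research
  gap.

Models are immutable after construction; alternative weightings are
expressed as separate :class:`~vetprio.ranking.WeightScheme` objects.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

from ._rounding import round_half_away

__all__ = [
    "ScoreScale",
    "SubCriterion",
    "CriterionSpec",
    "ModelSpec",
    "compute_weight",
    "build_default_prioritisation_model",
    "build_default_gap_model",
    "validate_model",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "slugify",
]

_NORMALISATION_TOL = 1e-9


def slugify(name: str) -> str:
    """Normalised ASCII slug for file names and CLI arguments."""
    text = unicodedata.normalize("NFKD", name).encode("ascii", "ignore").decode()
    text = re.sub(r"[^A-Za-z0-9]+", "_", text).strip("_").lower()
    return text


def compute_weight(max_score: int, n_levels: int) -> float:
    """Per-level weighting coefficient W = 100 / (max_score * n_levels).

    ``max_score`` is the maximum score of a level within the criterion
    and ``n_levels`` the number of levels, so that a criterion with all
    levels at the maximum totals exactly 100. The value is returned at
    full precision; :meth:`CriterionSpec.display_coefficient` applies
    the two-decimal display convention.

    Raises
    ------
    ValueError
        If either argument is not a positive integer.
    """
    if not isinstance(max_score, (int,)) or isinstance(max_score, bool):
        raise ValueError(f"max_score must be a positive integer, got {max_score!r}")
    if not isinstance(n_levels, (int,)) or isinstance(n_levels, bool):
        raise ValueError(f"n_levels must be a positive integer, got {n_levels!r}")
    if max_score < 1:
        raise ValueError(f"max_score must be >= 1, got {max_score}")
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    return 100.0 / (max_score * n_levels)


@dataclass(frozen=True)
class ScoreScale:
    """An ordered integer score scale, e.g. 0..4 or −2..+2."""

    allowed_values: tuple[int, ...]

    def __post_init__(self) -> None:
        values = tuple(int(v) for v in self.allowed_values)
        if not values:
            raise ValueError("ScoreScale requires at least one allowed value")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError(f"scale values must be strictly increasing: {values}")
        object.__setattr__(self, "allowed_values", values)

    @property
    def max_value(self) -> int:
        return self.allowed_values[-1]

    @property
    def min_value(self) -> int:
        return self.allowed_values[0]

    def __contains__(self, score: object) -> bool:
        return score in self.allowed_values

    @classmethod
    def from_range(cls, lo: int, hi: int) -> "ScoreScale":
        return cls(tuple(range(lo, hi + 1)))


@dataclass(frozen=True)
class SubCriterion:
    """One scored level within a criterion (1-based ``index``)."""

    name: str
    index: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("sub-criterion index is 1-based")


@dataclass(frozen=True)
class CriterionSpec:
    """A criterion: ordered sub-criteria, a scale and its coefficient.

    The coefficient is always derived from the scale maximum and the
    number of levels via :func:`compute_weight`; it is never supplied
    independently, which guarantees the normalisation invariant
    ``coefficient * max_score * n_levels == 100``.
    """

    name: str
    sub_criteria: tuple[SubCriterion, ...]
    scale: ScoreScale
    availability_marker: int | None = None  # 1-based sub-criterion index, gap areas only
    coefficient: float | None = None  # derived via compute_weight unless tampered with

    def __post_init__(self) -> None:
        subs = tuple(self.sub_criteria)
        if not subs:
            raise ValueError(f"criterion {self.name!r} has no sub-criteria")
        if list(s.index for s in subs) != list(range(1, len(subs) + 1)):
            raise ValueError(f"sub-criterion indices of {self.name!r} must be 1..I in order")
        if self.availability_marker is not None and not (
            1 <= self.availability_marker <= len(subs)
        ):
            raise ValueError(f"availability_marker out of range for {self.name!r}")
        object.__setattr__(self, "sub_criteria", subs)
        if self.coefficient is None:
            object.__setattr__(
                self, "coefficient", compute_weight(self.scale.max_value, len(subs))
            )

    @property
    def n_levels(self) -> int:
        return len(self.sub_criteria)

    @property
    def display_coefficient(self) -> float:
        """Coefficient rounded to two decimals, half away from zero."""
        return round_half_away(self.coefficient, 2)

    @property
    def slug(self) -> str:
        return slugify(self.name)

    def sub_criterion_names(self) -> list[str]:
        return [s.name for s in self.sub_criteria]


ModelKind = Literal["prioritisation", "gap"]


@dataclass(frozen=True)
class ModelSpec:
    """An ordered collection of criteria forming one scoring model."""

    model_kind: ModelKind
    criteria: tuple[CriterionSpec, ...]
    version: str = "1.0"

    def __post_init__(self) -> None:
        # duplicate criterion names are reported by validate_model, not
        # raised here, so invalid documents can be inspected whole
        object.__setattr__(self, "criteria", tuple(self.criteria))
        if self.model_kind not in ("prioritisation", "gap"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")

    def criterion(self, name: str) -> CriterionSpec:
        for c in self.criteria:
            if c.name == name or c.slug == name:
                return c
        raise KeyError(f"no criterion named {name!r}")

    def criterion_names(self) -> list[str]:
        return [c.name for c in self.criteria]

    @property
    def n_sub_criteria(self) -> int:
        return sum(c.n_levels for c in self.criteria)


def _criterion(
    name: str,
    scale: ScoreScale,
    sub_names: Sequence[str],
    availability_marker: int | None = None,
) -> CriterionSpec:
    subs = tuple(SubCriterion(n, i + 1) for i, n in enumerate(sub_names))
    return CriterionSpec(name, subs, scale, availability_marker)


_SCALE_0_4 = ScoreScale.from_range(0, 4)
_SCALE_PM2 = ScoreScale.from_range(-2, 2)


def build_default_prioritisation_model() -> ModelSpec:
    """The six-criterion prioritisation model.

    Sub-criterion counts (10, 3, 6, 3, 4, 3); the first five criteria
    use the 0..4 scale, control tools use −2..+2 (an effective existing
    tool subtracts from the total, a missing one adds to it).
    """
    return ModelSpec(
        model_kind="prioritisation",
        criteria=(
            _criterion(
                "Disease knowledge",
                _SCALE_0_4,
                [
                    "Speed of spread",
                    "Number of species involved",
                    "Persistence of infectious agent in the environment",
                    "Risk of spread to susceptible populations",
                    "Potential for silent spread",
                    "Wildlife reservoir and potential spread",
                    "Vector reservoir and potential spread",
                    "Variability of the agent",
                    "Understanding of fundamental immunology",
                    "Host pathogen interaction",
                ],
            ),
            _criterion(
                "Impact on animal health and welfare",
                _SCALE_0_4,
                [
                    "Disease impact on production",
                    "Duration of animal welfare impact",
                    "Proportion of animals affected and suffering pain/injury/distress"
                    " as a result of the disease",
                ],
            ),
            _criterion(
                "Impact on public health – human health",
                _SCALE_0_4,
                [
                    "Impact of occurrence on human health",
                    "Likelihood of occurrence",
                    "Impact of occurrence on food safety",
                    "Transmissibility (spread from animals to humans)",
                    "Spread in humans",
                    "Bioterrorism potential",
                ],
            ),
            _criterion(
                "Impact on wider society",
                _SCALE_0_4,
                [
                    "Economic direct impact (including cumulative cost, e.g. enzootic"
                    " vs. epizootic)",
                    "Economic indirect impact (social, market)",
                    "Agriterrorism potential",
                ],
            ),
            _criterion(
                "Impact on trade",
                _SCALE_0_4,
                [
                    "Impact on international trade due to existing regulations",
                    "Impact on EC trade due to existing regulations",
                    "Potential for regionalisation",
                    "Impact on security of food supply",
                ],
            ),
            _criterion(
                "Control tools",
                _SCALE_PM2,
                [
                    "Appropriate diagnostics",
                    "Appropriate vaccines",
                    "Appropriate pharmaceuticals",
                ],
            ),
        ),
    )


def build_default_gap_model() -> ModelSpec:
    """The three-area control-tool gap-analysis model.

    Sub-criterion counts (12, 11, 11), scale −2..+2 throughout. Each
    area's first sub-criterion is the availability item (marked): when
    no product exists, not even in development, the whole criterion is
    handled by the availability override in the scoring engine.
    """
    return ModelSpec(
        model_kind="gap",
        criteria=(
            _criterion(
                "Diagnostic tools",
                _SCALE_PM2,
                [
                    "Availability",
                    "Prevention and control - Differentiation of infected from"
                    " vaccinated (DIVA)",
                    "Strategic reserve",
                    "Capacity of production",
                    "Market potential",
                    "Affordable",
                    "Quality/stability durability",
                    "Sensitivity",
                    "Specificity",
                    "Reproducibility",
                    "Simplicity/ease of use",
                    "Speed",
                ],
                availability_marker=1,
            ),
            _criterion(
                "Vaccination tools",
                _SCALE_PM2,
                [
                    "Commercial availability",
                    "Monitoring for infection in a vaccinated population",
                    "Strategic reserve",
                    "Capacity of production",
                    "Market potential",
                    "Affordable",
                    "Quality/stability",
                    "Safety of vaccines",
                    "Efficacy",
                    "Immunity",
                    "Convenience of use",
                ],
                availability_marker=1,
            ),
            _criterion(
                "Pharmaceutical tools",
                _SCALE_PM2,
                [
                    "Availability",
                    "Prevention and control",
                    "Strategic reserve",
                    "Capacity of production",
                    "Market potential",
                    "Cost",
                    "Quality",
                    "Safety animal",
                    "Safety consumer/user concerns",
                    "Safety environment",
                    "Resistance",
                ],
                availability_marker=1,
            ),
        ),
    )


def validate_model(spec: ModelSpec) -> list[str]:
    """Return human-readable descriptions of every violated invariant.

    An empty list means the model is valid. Violations are returned,
    never raised, so callers can report all problems at once. The
    function is pure: calling it twice returns equal lists.
    """
    violations: list[str] = []
    names = [c.name for c in spec.criteria]
    for name in sorted({n for n in names if names.count(n) > 1}):
        violations.append(f"duplicate criterion name: {name!r}")
    if spec.model_kind == "prioritisation" and len(spec.criteria) != 6:
        violations.append(
            f"prioritisation model expects 6 criteria, found {len(spec.criteria)}"
        )
    if spec.model_kind == "gap" and len(spec.criteria) != 3:
        violations.append(f"gap model expects 3 criteria, found {len(spec.criteria)}")
    for c in spec.criteria:
        values = c.scale.allowed_values
        if any(b <= a for a, b in zip(values, values[1:])):
            violations.append(f"criterion {c.name!r}: scale values not strictly increasing")
        if c.scale.max_value != max(values):
            violations.append(f"criterion {c.name!r}: max_value inconsistent with scale")
        sub_names = [s.name for s in c.sub_criteria]
        if len(set(sub_names)) != len(sub_names):
            violations.append(f"criterion {c.name!r}: duplicate sub-criterion names")
        if c.n_levels < 1:
            violations.append(f"criterion {c.name!r}: must have at least one level")
        residual = abs(c.coefficient * c.scale.max_value * c.n_levels - 100.0)
        if residual > _NORMALISATION_TOL:
            violations.append(
                f"criterion {c.name!r}: coefficient * X * I deviates from 100"
                f" by {residual:.3g}"
            )
    return violations


# -- JSON serialisation -------------------------------------------------------
#
# The on-disk document stores structure only; the coefficient is recomputed
# from scale and level count on load, never trusted from the file.


def model_to_dict(spec: ModelSpec) -> dict:
    doc: dict = {
        "model_kind": spec.model_kind,
        "version": spec.version,
        "criteria": [],
    }
    for c in spec.criteria:
        entry: dict = {
            "name": c.name,
            "scale": {"values": list(c.scale.allowed_values)},
            "sub_criteria": c.sub_criterion_names(),
        }
        if c.availability_marker is not None:
            entry["availability_marker"] = c.availability_marker
        doc["criteria"].append(entry)
    return doc


def model_from_dict(doc: dict) -> ModelSpec:
    try:
        criteria = tuple(
            _criterion(
                entry["name"],
                ScoreScale(tuple(entry["scale"]["values"])),
                entry["sub_criteria"],
                entry.get("availability_marker"),
            )
            for entry in doc["criteria"]
        )
        return ModelSpec(
            model_kind=doc["model_kind"],
            criteria=criteria,
            version=str(doc.get("version", "1.0")),
        )
    except KeyError as exc:
        raise ValueError(f"model document missing required key: {exc}") from exc


def save_model(spec: ModelSpec, path: str | Path) -> None:
    from .io import atomic_write_text

    atomic_write_text(Path(path), json.dumps(model_to_dict(spec), indent=2) + "\n")


def load_model(path: str | Path) -> ModelSpec:
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))
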