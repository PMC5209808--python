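import numpy as np
import pytest

from vetprio.model_core import (
    ModelSpec,
    build_default_gap_model,
    build_default_prioritisation_model,
)
from vetprio.scoring import ScoreSheet


@pytest.fixture(scope="session")
def prio_model() -> ModelSpec:
    return build_default_prioritisation_model()


@pytest.fixture(scope="session")
def gap_model() -> ModelSpec:
    return build_default_gap_model()


def constant_sheet(
    model: ModelSpec,
    value: int | None = None,
    per_criterion: dict[str, int] | None = None,
    disease_id: str = "dx",
    category: str = "epizootic",
    flags: dict[str, str] | None = None,
) -> ScoreSheet:
    """Sheet with one constant score per criterion (``per_criterion``
    overrides ``value``; ``None`` means the criterion's maximum)."""
    scores = {}
    for crit in model.criteria:
        if per_criterion and crit.name in per_criterion:
            v = per_criterion[crit.name]
        elif value is not None:
            v = value
        else:
            v = crit.scale.max_value
        scores.update({(crit.name, s.name): v for s in crit.sub_criteria})
    return ScoreSheet(
        disease_id=disease_id,
        disease_name=disease_id.replace("_", " ").title(),
        category=category,
        scores=scores,
        availability_flags=flags or {},
    )


def random_sheet(
    rng: np.random.Generator,
    model: ModelSpec,
    disease_id: str = "dx",
    category: str | None = None,
    with_flags: bool = False,
) -> ScoreSheet:
    from vetprio.scoring import AVAILABILITY_FLAGS, CATEGORIES

    scores = {
        (crit.name, sub.name): int(rng.choice(crit.scale.allowed_values))
        for crit in model.criteria
        for sub in crit.sub_criteria
    }
    flags = {}
    if with_flags and model.model_kind == "gap":
        flags = {
            crit.name: str(rng.choice(AVAILABILITY_FLAGS)) for crit in model.criteria
        }
    return ScoreSheet(
        disease_id=disease_id,
        disease_name=disease_id,
        category=category or str(rng.choice(CATEGORIES)),
        scores=scores,
        availability_flags=flags,
    )


def naive_weighted_sums(sheet: ScoreSheet, model: ModelSpec) -> dict[str, float]:
    """Independent brute-force oracle: per-criterion Σ(score × coef)
    summed term by term, no shared code with the engine."""
    out: dict[str, float] = {}
    for crit in model.criteria:
        coef = 100.0 / (crit.scale.allowed_values[-1] * len(crit.sub_criteria))
        total = 0.0
        for sub in crit.sub_criteria:
            total += sheet.scores[(crit.name, sub.name)] * coef
        out[crit.name] = total
    return out
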