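"""Synthetic elicitation studies for end-to-end testing and
parameter-recovery experiments.

No raw per-expert scores were ever deposited for the real elicitation,
so the generator emulates its structure: a list of diseases split over
the three categories, one expert panel per disease (size Poisson around
a mean of about seven), a latent integer score per sub-criterion, and
noisy expert copies of that latent sheet. Category-level effects shift
latent scores for chosen (category, criterion) pairs — by default,
zoonoses are pushed up on the public-health criterion, mirroring the
pattern seen in real rankings.

Determinism: a single integer seed drives everything; per-disease
substreams are derived from (seed, disease index), so adding diseases
to a configuration never perturbs the sheets of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .elicitation import Expert, PanelScores
from .model_core import ModelSpec
from .ranking import rank
from .scoring import CATEGORIES, ScoreSheet, disease_total

__all__ = [
    "GeneratorConfig",
    "SyntheticStudy",
    "RecoveryReport",
    "allocate_categories",
    "generate_study",
    "recovery_report",
]

_ROLE_CYCLE = ("diagnostic", "epidemiology", "industry", "economics", "other")

#: Category split of the real 52-disease list (epizootic, food-producing
#: animal complexes, zoonoses).
_DEFAULT_PROPORTIONS = (17 / 52, 16 / 52, 19 / 52)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of a synthetic elicitation study.

    Defaults reproduce the real study's shape: 52 diseases in three
    categories, panels of about seven experts, and elevated latent
    public-health scores for zoonoses. ``expert_noise_sd`` is the
    standard deviation of the Gaussian perturbation added to the latent
    score before integer rounding and clamping to the scale.
    """

    n_diseases: int = 52
    category_proportions: tuple[float, float, float] = _DEFAULT_PROPORTIONS
    panel_size_mean: float = 7.0
    panel_size_min: int = 1
    expert_noise_sd: float = 0.5
    category_effects: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("zoonotic", "Impact on public health – human health"): 2.0
        }
    )
    availability_none_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 1:
            raise ValueError("n_diseases must be >= 1")
        props = tuple(float(p) for p in self.category_proportions)
        if len(props) != 3 or any(p < 0 for p in props):
            raise ValueError("category_proportions must be 3 non-negative reals")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"category_proportions must sum to 1, got {sum(props)}")
        if self.panel_size_min < 1:
            raise ValueError("panel_size_min must be >= 1")
        if self.panel_size_mean < self.panel_size_min:
            raise ValueError("panel_size_mean must be >= panel_size_min")
        if self.expert_noise_sd < 0:
            raise ValueError("expert_noise_sd must be >= 0")
        if not 0.0 <= self.availability_none_prob <= 1.0:
            raise ValueError("availability_none_prob must be in [0, 1]")
        object.__setattr__(self, "category_proportions", props)
        object.__setattr__(self, "category_effects", dict(self.category_effects))


@dataclass(frozen=True)
class SyntheticStudy:
    """Output bundle of :func:`generate_study`."""

    prioritisation_panels: tuple[PanelScores, ...]
    gap_panels: tuple[PanelScores, ...]
    latent_prioritisation: tuple[ScoreSheet, ...]
    latent_gap: tuple[ScoreSheet, ...]


def allocate_categories(n: int, proportions: Sequence[float]) -> list[int]:
    """Deterministic largest-remainder allocation of ``n`` diseases to
    categories. Returns per-category counts summing to ``n``; ties in
    remainder go to the earlier category."""
    quotas = [n * p for p in proportions]
    counts = [int(q) for q in quotas]
    shortfall = n - sum(counts)
    remainders = sorted(
        range(len(proportions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


def _disease_rng(seed: int, disease_index: int) -> np.random.Generator:
    # keyed substream: adding diseases never perturbs earlier ones
    return np.random.default_rng(np.random.SeedSequence([seed, disease_index]))


def _latent_scores(
    rng: np.random.Generator, model: ModelSpec, category: str, effects: Mapping
) -> dict[tuple[str, str], int]:
    scores: dict[tuple[str, str], int] = {}
    for crit in model.criteria:
        values = crit.scale.allowed_values
        shift = float(effects.get((category, crit.name), 0.0))
        for sub in crit.sub_criteria:
            base = int(rng.choice(values))
            shifted = int(round(base + shift))
            scores[(crit.name, sub.name)] = _clamp_to_scale(shifted, values)
    return scores


def _clamp_to_scale(value: int, values: tuple[int, ...]) -> int:
    return max(values[0], min(values[-1], value))


def _noisy_copy(
    rng: np.random.Generator,
    latent: ScoreSheet,
    model: ModelSpec,
    sd: float,
) -> dict[tuple[str, str], int]:
    scores: dict[tuple[str, str], int] = {}
    for crit in model.criteria:
        values = crit.scale.allowed_values
        for sub in crit.sub_criteria:
            key = (crit.name, sub.name)
            noise = int(np.rint(rng.normal(0.0, sd))) if sd > 0 else 0
            scores[key] = _clamp_to_scale(latent.scores[key] + noise, values)
    return scores


def _make_panel(
    rng: np.random.Generator,
    latent: ScoreSheet,
    model: ModelSpec,
    config: GeneratorConfig,
) -> PanelScores:
    size = max(config.panel_size_min, int(rng.poisson(config.panel_size_mean)))
    experts = []
    for j in range(size):
        # first four experts take the four required roles, extras rotate
        role = _ROLE_CYCLE[j] if j < 4 else _ROLE_CYCLE[int(rng.integers(len(_ROLE_CYCLE)))]
        sheet = replace(
            latent, scores=_noisy_copy(rng, latent, model, config.expert_noise_sd)
        )
        experts.append(Expert(f"{latent.disease_id}-e{j + 1}", role, sheet))
    return PanelScores(disease_id=latent.disease_id, experts=tuple(experts))


def generate_study(
    config: GeneratorConfig, model: ModelSpec, gap_model: ModelSpec
) -> SyntheticStudy:
    """Generate one synthetic study: prioritisation panels, gap-scoring
    panels, and the latent truth sheets behind them.

    For each disease: a category (largest-remainder allocation of the
    configured proportions), a latent integer score per sub-criterion
    (uniform over the scale, shifted by any category effect, clamped),
    a panel size (Poisson, floored at ``panel_size_min``), and one
    noisy expert sheet per panel member. Gap sheets additionally draw
    per-area availability flags (``none`` with probability
    ``availability_none_prob``, otherwise split evenly between
    ``available`` and ``in_development``). Fully reproducible from
    ``config.seed``.
    """
    if model.model_kind != "prioritisation":
        raise ValueError("model must be of the prioritisation kind")
    if gap_model.model_kind != "gap":
        raise ValueError("gap_model must be of the gap kind")

    counts = allocate_categories(config.n_diseases, config.category_proportions)
    categories = [
        cat for cat, count in zip(CATEGORIES, counts) for _ in range(count)
    ]

    prio_panels: list[PanelScores] = []
    gap_panels: list[PanelScores] = []
    latent_prio: list[ScoreSheet] = []
    latent_gap: list[ScoreSheet] = []
    for i in range(config.n_diseases):
        rng = _disease_rng(config.seed, i)
        category = categories[i]
        disease_id = f"D{i + 1:03d}"
        name = f"Synthetic disease {i + 1:03d}"

        latent_p = ScoreSheet(
            disease_id=disease_id,
            disease_name=name,
            category=category,
            scores=_latent_scores(rng, model, category, config.category_effects),
        )
        flags = {}
        for crit in gap_model.criteria:
            if rng.random() < config.availability_none_prob:
                flags[crit.name] = "none"
            else:
                flags[crit.name] = (
                    "available" if rng.random() < 0.5 else "in_development"
                )
        latent_g = ScoreSheet(
            disease_id=disease_id,
            disease_name=name,
            category=category,
            scores=_latent_scores(rng, gap_model, category, config.category_effects),
            availability_flags=flags,
        )
        latent_prio.append(latent_p)
        latent_gap.append(latent_g)
        prio_panels.append(_make_panel(rng, latent_p, model, config))
        gap_panels.append(_make_panel(rng, latent_g, gap_model, config))

    return SyntheticStudy(
        prioritisation_panels=tuple(prio_panels),
        gap_panels=tuple(gap_panels),
        latent_prioritisation=tuple(latent_prio),
        latent_gap=tuple(latent_gap),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """How well aggregated consensus sheets recover the latent truth."""

    exact_match_fraction: float
    exact_match_by_sub_criterion: Mapping[tuple[str, str], float]
    mean_absolute_error: float
    top_k_overlap: float
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "exact_match_by_sub_criterion", dict(self.exact_match_by_sub_criterion)
        )


def recovery_report(
    latent: Sequence[ScoreSheet],
    aggregated: Sequence[ScoreSheet],
    model: ModelSpec,
    k: int = 10,
) -> RecoveryReport:
    """Compare aggregated sheets against the latent truth.

    Reports the per-sub-criterion and overall exact-match fraction, the
    mean absolute error over all scores, and the overlap between the
    top-``k`` diseases of the latent and recovered overall rankings
    (``|top_k(latent) ∩ top_k(aggregated)| / k``, computed on
    prioritisation totals). Noiseless generation recovers the truth
    exactly: match fraction 1, MAE 0, overlap 1.
    """
    truth = {s.disease_id: s for s in latent}
    recovered = {s.disease_id: s for s in aggregated}
    if set(truth) != set(recovered):
        raise ValueError(
            "latent and aggregated sheets cover different diseases:"
            f" {sorted(set(truth) ^ set(recovered))}"
        )
    k = min(k, len(truth))

    keys = [
        (crit.name, sub.name)
        for crit in model.criteria
        for sub in crit.sub_criteria
    ]
    match_by_key: dict[tuple[str, str], float] = {}
    abs_errors: list[int] = []
    matches = 0
    for key in keys:
        hits = 0
        for did in truth:
            a, b = truth[did].scores[key], recovered[did].scores[key]
            hits += int(a == b)
            abs_errors.append(abs(a - b))
        match_by_key[key] = hits / len(truth)
        matches += hits
    n_cells = len(keys) * len(truth)

    if model.model_kind == "prioritisation":
        totals_fn = lambda sheets: [disease_total(s, model) for s in sheets]
        top = lambda sheets: set(
            rank(totals_fn(sheets), "overall").disease_ids()[:k]
        )
        overlap = len(top(list(truth.values())) & top(list(recovered.values()))) / k
    else:
        overlap = float("nan")

    return RecoveryReport(
        exact_match_fraction=matches / n_cells,
        exact_match_by_sub_criterion=match_by_key,
        mean_absolute_error=float(np.mean(abs_errors)),
        top_k_overlap=overlap,
        k=k,
    )
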