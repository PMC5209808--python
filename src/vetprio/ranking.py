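"""Rankings of diseases by overall score, within disease categories or
by a single criterion, plus robustness of rankings under alternative
weight schemes.

Equal weights across criteria are a modelling choice, not a law:
different stakeholders (public-health funders, trade bodies, producers)
may weight the criteria differently, which can reorder the list. A
:class:`WeightScheme` replaces the default per-level coefficients by
arbitrary per-criterion weights, and :func:`rank_concordance` (Kendall
tau-b) quantifies how far the reordering goes.

Tie semantics are competition ranking: equal scores share the same
rank, the next rank is skipped (1, 2, 2, 4), and tied entries are
listed alphabetically by disease name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import scipy.stats

from .model_core import ModelSpec
from .scoring import CATEGORIES, DiseaseTotal, GapTotals, ScoreSheet, criterion_total

__all__ = [
    "RankingTable",
    "RankingEntry",
    "WeightScheme",
    "rank",
    "rank_gaps",
    "reweight",
    "rank_concordance",
]


@dataclass(frozen=True)
class RankingEntry:
    disease_id: str
    disease_name: str
    score: float
    rank: int


@dataclass(frozen=True)
class RankingTable:
    """Ordered (disease, score, rank) entries for one scope.

    ``scope`` is ``"overall"``, ``"category:<label>"`` or
    ``"criterion:<name>"``.
    """

    scope: str
    entries: tuple[RankingEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def disease_ids(self) -> list[str]:
        return [e.disease_id for e in self.entries]

    def position(self, disease_id: str) -> int:
        """0-based list position (not the competition rank)."""
        for i, e in enumerate(self.entries):
            if e.disease_id == disease_id:
                return i
        raise KeyError(disease_id)


@dataclass(frozen=True)
class WeightScheme:
    """An alternative criterion → weight assignment."""

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        weights = {str(k): float(v) for k, v in self.weights.items()}
        if any(w < 0 for w in weights.values()):
            raise ValueError(f"scheme {self.name!r} has negative weights")
        if not any(w > 0 for w in weights.values()):
            raise ValueError(f"scheme {self.name!r} needs at least one positive weight")
        object.__setattr__(self, "weights", weights)


def _build_table(
    scope: str, rows: Sequence[tuple[str, str, float]]
) -> RankingTable:
    """Competition-rank rows of (disease_id, disease_name, score)."""
    ordered = sorted(rows, key=lambda r: (-r[2], r[1], r[0]))
    entries: list[RankingEntry] = []
    last_score: float | None = None
    last_rank = 0
    for pos, (did, name, score) in enumerate(ordered, start=1):
        if last_score is not None and score == last_score:
            rank_value = last_rank
        else:
            rank_value = pos
        entries.append(RankingEntry(did, name, score, rank_value))
        last_score, last_rank = score, rank_value
    return RankingTable(scope=scope, entries=tuple(entries))


def rank(totals: Sequence[DiseaseTotal], scope: str = "overall") -> RankingTable:
    """Rank diseases by overall score, or within a scope.

    ``scope="category:<label>"`` restricts to one disease category
    (labels: epizootic, food_producing_complex, zoonotic);
    ``scope="criterion:<name>"`` ranks all diseases by that criterion's
    weighted total alone.
    """
    if not totals:
        raise ValueError("rank requires at least one disease total")
    ids = [t.disease_id for t in totals]
    if len(set(ids)) != len(ids):
        raise ValueError("disease_ids must be unique")

    selected = list(totals)
    if scope == "overall":
        key = lambda t: t.overall
    elif scope.startswith("category:"):
        label = scope.split(":", 1)[1]
        if label not in CATEGORIES:
            raise ValueError(f"unknown category {label!r}; expected one of {CATEGORIES}")
        if any(t.category is None for t in totals):
            raise ValueError("category scope requires category labels on inputs")
        selected = [t for t in totals if t.category == label]
        key = lambda t: t.overall
    elif scope.startswith("criterion:"):
        name = scope.split(":", 1)[1]
        missing = [t.disease_id for t in totals if name not in t.per_criterion]
        if missing:
            raise ValueError(f"criterion {name!r} absent from totals of {missing}")
        key = lambda t: t.per_criterion[name]
    else:
        raise ValueError(f"unknown scope {scope!r}")

    rows = [(t.disease_id, t.disease_name, float(key(t))) for t in selected]
    return _build_table(scope, rows)


def rank_gaps(gaps: Sequence[GapTotals], area: str) -> RankingTable:
    """Rank diseases by one gap area's integer score, descending
    (largest gap first), with the same tie semantics as :func:`rank`."""
    if not gaps:
        raise ValueError("rank_gaps requires at least one gap total")
    ids = [g.disease_id for g in gaps]
    if len(set(ids)) != len(ids):
        raise ValueError("disease_ids must be unique")
    rows = [(g.disease_id, g.disease_name, float(g.area(area))) for g in gaps]
    return _build_table(f"criterion:{area}", rows)


def reweight(
    sheets: Sequence[ScoreSheet], model: ModelSpec, scheme: WeightScheme
) -> list[DiseaseTotal]:
    """Recompute disease totals under an alternative weight scheme.

    Each criterion contributes ``(raw score sum) × scheme weight``; a
    scheme equal to the default coefficients reproduces the standard
    totals exactly, and scaling all weights by a common positive
    constant leaves the ranking unchanged.
    """
    missing = [c.name for c in model.criteria if c.name not in scheme.weights]
    if missing:
        raise ValueError(f"scheme {scheme.name!r} misses criteria: {missing}")
    out: list[DiseaseTotal] = []
    for sheet in sheets:
        per: dict[str, float] = {}
        for crit in model.criteria:
            raw = criterion_total(sheet, crit) / crit.coefficient
            per[crit.name] = raw * scheme.weights[crit.name]
        out.append(
            DiseaseTotal(
                disease_id=sheet.disease_id,
                per_criterion=per,
                overall=sum(per.values()),
                disease_name=sheet.disease_name,
                category=sheet.category,
            )
        )
    return out


def rank_concordance(a: RankingTable, b: RankingTable) -> float:
    """Kendall tau-b between two rankings of the same disease set.

    1 for identical orderings, −1 for an exact reversal without ties;
    ties are handled by the tau-b correction. Raises ``ValueError`` if
    the tables cover different disease sets.
    """
    ids_a, ids_b = set(a.disease_ids()), set(b.disease_ids())
    if ids_a != ids_b:
        raise ValueError(
            "rankings cover different disease sets:"
            f" only-in-a={sorted(ids_a - ids_b)}, only-in-b={sorted(ids_b - ids_a)}"
        )
    rank_a = {e.disease_id: e.rank for e in a.entries}
    rank_b = {e.disease_id: e.rank for e in b.entries}
    order = sorted(ids_a)
    xs = [rank_a[d] for d in order]
    ys = [rank_b[d] for d in order]
    if len(order) == 1:
        return 1.0
    tau = scipy.stats.kendalltau(xs, ys, variant="b").statistic
    return float(tau)
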