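"""Readers and writers for score sheets, panels and rankings, plus the
packaged reference-table fixtures.

CSV dialect: UTF-8, comma delimiter, header row, "." decimal separator.
The Unicode minus sign (U+2212), common in typeset tables, is accepted
on input wherever an integer score is expected; ASCII hyphen-minus is
always emitted on output. All writers go through a temp-file +
atomic-rename path so a failed write never leaves a partial file.

Fixtures transcribe the published reference tables once, by hand; each
file's SHA-256 is recorded and verified on load, so silent corruption
of the packaged data raises rather than propagating wrong numbers.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .elicitation import DissentRecord, Expert, PanelScores
from .model_core import ModelSpec, load_model
from .ranking import RankingTable
from .scoring import (
    CATEGORIES,
    DiseaseTotal,
    GapTotals,
    ScoreSheet,
    SheetValidationError,
    validate_sheet,
)

__all__ = [
    "FIXTURE_IDS",
    "Fixture",
    "CorruptFixtureError",
    "load_fixture",
    "fixture_totals",
    "fixture_gap_totals",
    "read_sheets",
    "write_sheets",
    "read_panels",
    "write_panels",
    "write_ranking",
    "write_dissent",
    "atomic_write_text",
]

_FIXTURE_DIR = Path(__file__).parent / "fixtures"

FIXTURE_IDS = (
    "table2_model",
    "table3_model",
    "table4_overall",
    "table5_by_category",
    "table6_gaps",
)

_FIXTURE_FILES = {
    "table2_model": "table2_model.json",
    "table3_model": "table3_model.json",
    "table4_overall": "table4_overall.csv",
    "table5_by_category": "table5_by_category.csv",
    "table6_gaps": "table6_gaps.csv",
}


class CorruptFixtureError(RuntimeError):
    """A packaged fixture's checksum does not match its manifest entry."""


@dataclass(frozen=True)
class Fixture:
    table_id: str
    payload: object


def atomic_write_text(path: Path, text: str) -> None:
    """Write text to ``path`` via a temp file and atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _fixture_path(table_id: str) -> Path:
    if table_id not in _FIXTURE_FILES:
        raise ValueError(f"unknown fixture {table_id!r}; known: {FIXTURE_IDS}")
    return _FIXTURE_DIR / _FIXTURE_FILES[table_id]


def _verify_checksum(table_id: str, path: Path) -> None:
    manifest = json.loads((_FIXTURE_DIR / "checksums.json").read_text())
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if manifest[path.name] != digest:
        raise CorruptFixtureError(
            f"fixture {table_id!r} ({path.name}) checksum mismatch:"
            f" expected {manifest[path.name]}, found {digest}"
        )


def load_fixture(table_id: str) -> Fixture:
    """Load one packaged reference table.

    ``table2_model``/``table3_model`` return a :class:`ModelSpec`; the
    three score tables return a validated ``pandas.DataFrame``.
    """
    path = _fixture_path(table_id)
    _verify_checksum(table_id, path)
    if table_id in ("table2_model", "table3_model"):
        return Fixture(table_id, load_model(path))

    df = pd.read_csv(path)
    if table_id == "table4_overall":
        if len(df) != 52 or df["disease_id"].duplicated().any():
            raise CorruptFixtureError("overall-ranking fixture must list 52 unique diseases")
    elif table_id == "table5_by_category":
        if len(df) != 52 or set(df["category"]) != set(CATEGORIES):
            raise CorruptFixtureError(
                "by-category fixture must partition 52 diseases into 3 categories"
            )
    elif table_id == "table6_gaps":
        counts = df.groupby("category").size()
        if len(df) != 30 or not (counts == 10).all():
            raise CorruptFixtureError("gap fixture must list 10 diseases per category")
    return Fixture(table_id, df)


def fixture_totals() -> list[DiseaseTotal]:
    """The published overall scores as :class:`DiseaseTotal` objects.

    The printed integers are already-rounded published values; their
    per-criterion decomposition is not public, so ``per_criterion``
    carries only the published overall.
    """
    df = load_fixture("table4_overall").payload
    return [
        DiseaseTotal(
            disease_id=row.disease_id,
            per_criterion={"published overall": float(row.overall_score)},
            overall=float(row.overall_score),
            disease_name=row.disease_name,
            category=row.category,
        )
        for row in df.itertuples()
    ]


def fixture_gap_totals() -> list[GapTotals]:
    """The published gap scores as :class:`GapTotals` objects."""
    df = load_fixture("table6_gaps").payload
    return [
        GapTotals(
            disease_id=row.disease_id,
            diagnostics=int(row.diagnostics),
            vaccines=int(row.vaccines),
            pharmaceuticals=int(row.pharmaceuticals),
            disease_name=row.disease_name,
            category=row.category,
        )
        for row in df.itertuples()
    ]


# -- score-sheet CSV ----------------------------------------------------------

_SHEET_COLUMNS = [
    "disease_id",
    "disease_name",
    "category",
    "criterion",
    "sub_criterion",
    "score",
    "availability_flag",
]


def _parse_int(text: str) -> int:
    return int(str(text).strip().replace("−", "-"))


def read_sheets(path: str | Path, model: ModelSpec) -> list[ScoreSheet]:
    """Read score sheets from long-format CSV and validate them against
    ``model``. Malformed rows raise a :class:`SheetValidationError`
    listing the offending line numbers (1-based, header = line 1)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _SHEET_COLUMNS[:6] if c not in df.columns]
    if missing_cols:
        raise SheetValidationError(f"{path}: missing columns {missing_cols}")

    errors: list[str] = []
    per_disease: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            score = _parse_int(row.score)
        except ValueError:
            errors.append(f"line {i}: score {row.score!r} is not an integer")
            continue
        entry = per_disease.setdefault(
            row.disease_id,
            {
                "disease_name": row.disease_name,
                "category": row.category,
                "scores": {},
                "flags": {},
                "line": i,
            },
        )
        key = (row.criterion, row.sub_criterion)
        if key in entry["scores"]:
            errors.append(f"line {i}: duplicate entry for {key}")
        entry["scores"][key] = score
        flag = getattr(row, "availability_flag", "")
        if flag:
            prev = entry["flags"].get(row.criterion)
            if prev is not None and prev != flag:
                errors.append(
                    f"line {i}: conflicting availability flags for {row.criterion!r}"
                )
            entry["flags"][row.criterion] = flag
    if errors:
        raise SheetValidationError(f"{path}: " + "; ".join(errors))

    sheets: list[ScoreSheet] = []
    for did, entry in per_disease.items():
        try:
            sheet = ScoreSheet(
                disease_id=did,
                disease_name=entry["disease_name"],
                category=entry["category"],
                scores=entry["scores"],
                availability_flags=entry["flags"],
            )
            validate_sheet(sheet, model)
        except SheetValidationError as exc:
            raise SheetValidationError(
                f"{path}, disease starting at line {entry['line']}: {exc}"
            ) from exc
        sheets.append(sheet)
    return sheets


def _sheet_rows(sheet: ScoreSheet, model: ModelSpec) -> list[dict]:
    rows = []
    for crit in model.criteria:
        flag = sheet.availability_flags.get(crit.name, "")
        for sub in crit.sub_criteria:
            rows.append(
                {
                    "disease_id": sheet.disease_id,
                    "disease_name": sheet.disease_name,
                    "category": sheet.category,
                    "criterion": crit.name,
                    "sub_criterion": sub.name,
                    "score": sheet.scores[(crit.name, sub.name)],
                    "availability_flag": flag,
                }
            )
    return rows


def write_sheets(sheets: Sequence[ScoreSheet], model: ModelSpec, path: str | Path) -> None:
    rows = [r for s in sheets for r in _sheet_rows(s, model)]
    df = pd.DataFrame(rows, columns=_SHEET_COLUMNS)
    atomic_write_text(Path(path), df.to_csv(index=False))


# -- panel CSV ----------------------------------------------------------------

_PANEL_COLUMNS = _SHEET_COLUMNS[:3] + ["expert_id", "role"] + _SHEET_COLUMNS[3:]


def write_panels(panels: Sequence[PanelScores], model: ModelSpec, path: str | Path) -> None:
    rows = []
    for panel in panels:
        for expert in panel.experts:
            for r in _sheet_rows(expert.sheet, model):
                rows.append({**r, "expert_id": expert.expert_id, "role": expert.role})
    df = pd.DataFrame(rows, columns=_PANEL_COLUMNS)
    atomic_write_text(Path(path), df.to_csv(index=False))


def read_panels(path: str | Path, model: ModelSpec) -> list[PanelScores]:
    """Read per-expert sheets from CSV and group them into one panel per
    disease, preserving first-appearance disease order."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = {"disease_id", "expert_id", "role", "criterion", "sub_criterion", "score"}
    missing = sorted(needed - set(df.columns))
    if missing:
        raise SheetValidationError(f"{path}: missing columns {missing}")

    panels: list[PanelScores] = []
    for did in df["disease_id"].unique():
        sub = df[df["disease_id"] == did]
        experts = []
        for eid in sub["expert_id"].unique():
            rows = sub[sub["expert_id"] == eid]
            scores = {
                (r.criterion, r.sub_criterion): _parse_int(r.score)
                for r in rows.itertuples(index=False)
            }
            flags = {
                r.criterion: r.availability_flag
                for r in rows.itertuples(index=False)
                if getattr(r, "availability_flag", "")
            }
            first = rows.iloc[0]
            sheet = ScoreSheet(
                disease_id=did,
                disease_name=first.get("disease_name", did) or did,
                category=first["category"],
                scores=scores,
                availability_flags=flags,
            )
            validate_sheet(sheet, model)
            experts.append(Expert(eid, first["role"], sheet))
        panels.append(PanelScores(disease_id=did, experts=tuple(experts)))
    return panels


# -- ranking / dissent output -------------------------------------------------


def _ranking_frame(table: RankingTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": e.rank,
                "disease_id": e.disease_id,
                "disease_name": e.disease_name,
                "score": e.score,
            }
            for e in table.entries
        ]
    )


def write_ranking(table: RankingTable, path: str | Path, format: str = "csv") -> None:
    """Export a ranking as ``csv``, ``json`` or a fixed-width ``txt``
    table mirroring the published presentation."""
    df = _ranking_frame(table)
    if format == "csv":
        atomic_write_text(Path(path), df.to_csv(index=False))
    elif format == "json":
        doc = {"scope": table.scope, "entries": df.to_dict(orient="records")}
        atomic_write_text(Path(path), json.dumps(doc, indent=2) + "\n")
    elif format == "txt":
        name_w = max([len("Disease")] + [len(e.disease_name) for e in table.entries])
        lines = [f"Scope: {table.scope}", f"{'Rank':>4}  {'Disease':<{name_w}}  Score"]
        for e in table.entries:
            score = f"{e.score:g}"
            lines.append(f"{e.rank:>4}  {e.disease_name:<{name_w}}  {score:>6}")
        atomic_write_text(Path(path), "\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown ranking format {format!r}")


def write_dissent(records: Sequence[DissentRecord], path: str | Path) -> None:
    """Export dissent records as a 'gaps identified' CSV."""
    df = pd.DataFrame(
        [
            {
                "disease_id": r.disease_id,
                "criterion": r.criterion,
                "sub_criterion": r.sub_criterion,
                "expert_scores": " ".join(str(s) for s in r.expert_scores),
                "range": r.range,
                "consensus_value": r.consensus_value,
            }
            for r in records
        ],
        columns=[
            "disease_id",
            "criterion",
            "sub_criterion",
            "expert_scores",
            "range",
            "consensus_value",
        ],
    )
    atomic_write_text(Path(path), df.to_csv(index=False))
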