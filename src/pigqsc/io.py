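"""File formats and report rendering.

All tabular formats are comma-separated UTF-8 text with "." as the decimal
separator.  Assessments travel as YAML documents (one farm per file: a
``responses`` mapping plus a ``rooms`` list).  Rendered reports round to two
decimals at presentation time only; stored tables keep full precision.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import analytics
from .analytics import (
    GROUP_LABELS,
    GroupComparison,
    KPI_COLUMNS,
    OVERALL_COLUMN,
    SCORE_COLUMNS,
)
from .errors import ContractError, SchemaFormatError
from .schema import CalculatorSchema
from .scoring import FactorResponse, FarmAssessment, RoomAssessment, ScoreCard

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "COHORT_COLUMNS",
    "read_cohort_table",
    "write_cohort_table",
    "scorecards_to_frame",
    "cohort_frame",
    "read_assessment",
    "write_assessment",
    "read_assessments_long",
    "render_scorecard",
    "render_descriptives",
    "render_correlations",
    "render_group_comparison",
    "render_farm_panel",
]

#: the documented column dictionary of a full cohort table
COHORT_COLUMNS = ("farm_id", *SCORE_COLUMNS, OVERALL_COLUMN, *KPI_COLUMNS)


@dataclass(frozen=True)
class RunConfig:
    """Run-wide options shared by the CLI subcommands."""

    schema_path: str | None = None
    percentile_method: str = "haverage"
    strict: bool = True
    alpha: float = 0.05
    out_dir: str = "."
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ContractError(f"alpha must be in (0,1), got {self.alpha}")


# ---------------------------------------------------------------------------
# cohort tables

def read_cohort_table(path, required=COHORT_COLUMNS) -> pd.DataFrame:
    """Read a farms x (scores + KPIs) table, validating the column dictionary.

    Unknown columns and missing required columns are format errors listing
    the offenders; a non-numeric cell is reported with its row and column.
    """
    df = pd.read_csv(path, dtype={"farm_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaFormatError(f"{path}: missing column(s) {missing}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise SchemaFormatError(f"{path}: unknown column(s) {unknown} "
                                f"(documented columns: {list(COHORT_COLUMNS)})")
    for col in df.columns:
        if col == "farm_id":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaFormatError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r}, row {int(bad[0]) + 2} (1-based, counting the header)")
        df[col] = coerced
    if df["farm_id"].duplicated().any():
        dups = sorted(df.loc[df["farm_id"].duplicated(), "farm_id"].unique())
        raise ContractError(f"{path}: duplicate farm_id(s) {dups}")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def scorecards_to_frame(scorecards: list[ScoreCard]) -> pd.DataFrame:
    """One row per farm: farm_id, the ten index scores, overall."""
    rows = []
    for card in scorecards:
        row = {"farm_id": card.farm_id}
        for col, s in zip(SCORE_COLUMNS, card.index_scores):
            row[col] = s.points
        row[OVERALL_COLUMN] = card.overall
        rows.append(row)
    return pd.DataFrame(rows, columns=["farm_id", *SCORE_COLUMNS, OVERALL_COLUMN])


def cohort_frame(scorecards: list[ScoreCard], kpis: pd.DataFrame) -> pd.DataFrame:
    """Join score cards with a KPI table on farm_id into one cohort table."""
    scores = scorecards_to_frame(scorecards)
    if "farm_id" not in kpis.columns:
        raise ContractError("KPI table must carry a farm_id column")
    merged = scores.merge(kpis, on="farm_id", how="inner", validate="1:1")
    if len(merged) != len(scores):
        missing = set(scores["farm_id"]) - set(kpis["farm_id"])
        raise ContractError(f"KPI table misses farm(s) {sorted(missing)}")
    return merged


# ---------------------------------------------------------------------------
# assessments (YAML)

def _response_value(resp: FactorResponse):
    return None if resp.missing else resp.value


def write_assessment(assessment: FarmAssessment, path) -> None:
    doc = {
        "farm_id": assessment.farm_id,
        "visit_date": (assessment.visit_date.isoformat()
                       if assessment.visit_date else None),
        "responses": {fid: _response_value(r)
                      for fid, r in assessment.farm_responses.items()},
        "rooms": [
            {"room_id": room.room_id,
             "responses": {fid: _response_value(r)
                           for fid, r in room.responses.items()}}
            for room in assessment.rooms
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def _parse_responses(node, where: str) -> dict[str, FactorResponse]:
    if not isinstance(node, dict):
        raise SchemaFormatError(f"{where}: 'responses' must be a mapping")
    out = {}
    for fid, value in node.items():
        fid = str(fid)
        out[fid] = FactorResponse(fid, value, missing=value is None)
    return out


def read_assessment(path) -> FarmAssessment:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemaFormatError(f"{path}: does not parse: {exc}") from exc
    if not isinstance(doc, dict) or "farm_id" not in doc:
        raise SchemaFormatError(f"{path}: expected a mapping with a farm_id")
    unknown = set(doc) - {"farm_id", "visit_date", "responses", "rooms"}
    if unknown:
        raise SchemaFormatError(f"{path}: unknown field(s) {sorted(unknown)}")
    visit = doc.get("visit_date")
    if isinstance(visit, str):
        visit = _dt.date.fromisoformat(visit)
    rooms = []
    for i, rnode in enumerate(doc.get("rooms") or []):
        if not isinstance(rnode, dict) or "room_id" not in rnode:
            raise SchemaFormatError(f"{path}: rooms[{i}] needs a room_id")
        rooms.append(RoomAssessment(
            room_id=str(rnode["room_id"]),
            responses=_parse_responses(rnode.get("responses") or {},
                                       f"{path}: rooms[{i}]")))
    return FarmAssessment(
        farm_id=str(doc["farm_id"]),
        farm_responses=_parse_responses(doc.get("responses") or {}, str(path)),
        rooms=rooms,
        visit_date=visit,
    )


_TRUE = {"true", "yes", "1"}
_FALSE = {"false", "no", "0"}


def _parse_long_value(raw: str):
    s = str(raw).strip()
    low = s.lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    try:
        return float(s)
    except ValueError:
        return s  # categorical option label


def read_assessments_long(path) -> list[FarmAssessment]:
    """Batch-entry alternative: one CSV with columns
    farm_id, room_id, factor_id, value.

    ``room_id`` is the literal ``farm`` for farm-level factors.  Values parse
    as yes/no -> bool, numbers -> float, anything else -> option label.
    Farms appear in first-occurrence order.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["farm_id", "room_id", "factor_id", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaFormatError(f"{path}: missing column(s) {missing}")
    farms: dict[str, FarmAssessment] = {}
    for row in df.itertuples(index=False):
        farm = farms.setdefault(
            row.farm_id,
            FarmAssessment(farm_id=row.farm_id, farm_responses={}, rooms=[]))
        value = _parse_long_value(row.value)
        resp = FactorResponse(row.factor_id, value)
        if str(row.room_id).lower() == "farm":
            if row.factor_id in farm.farm_responses:
                raise ContractError(f"{path}: duplicate factor {row.factor_id!r} "
                                    f"for farm {row.farm_id!r}")
            farm.farm_responses[row.factor_id] = resp
        else:
            room = next((r for r in farm.rooms if r.room_id == row.room_id), None)
            if room is None:
                room = RoomAssessment(room_id=str(row.room_id), responses={})
                farm.rooms.append(room)
            if row.factor_id in room.responses:
                raise ContractError(f"{path}: duplicate factor {row.factor_id!r} "
                                    f"in farm {row.farm_id!r} room {row.room_id!r}")
            room.responses[row.factor_id] = resp
    return list(farms.values())


# ---------------------------------------------------------------------------
# report rendering (deterministic, 2-decimal presentation)

def _fmt(x: float) -> str:
    return f"{x:.2f}"


def render_scorecard(card: ScoreCard, schema: CalculatorSchema | None = None) -> str:
    lines = [f"Farm {card.farm_id}", "-" * 40]
    for s in card.index_scores:
        lines.append(f"{s.index_id:>2}. {s.name[:50]:<52} {_fmt(s.points):>6}")
    lines.append("-" * 40)
    lines.append(f"{'Overall score (0-100)':<56} {_fmt(card.overall):>6}")
    return "\n".join(lines) + "\n"


def render_descriptives(table: pd.DataFrame) -> str:
    """Benchmark table: Mean SD Min Max P25 P50 P75 per variable."""
    cols = ["mean", "sd", "min", "max", "p25", "p50", "p75"]
    header = f"{'variable':<34}" + "".join(f"{c:>9}" for c in cols)
    lines = [header]
    for var, row in table.iterrows():
        lines.append(f"{str(var):<34}" + "".join(f"{row[c]:>9.2f}" for c in cols))
    return "\n".join(lines) + "\n"


def render_correlations(table: analytics.CorrelationTable) -> str:
    """Correlation matrix with stars; footnote documents the star rule."""
    text = table.to_text_frame()
    width = max(12, *(len(str(c)) + 2 for c in text.columns))
    header = f"{'score':<22}" + "".join(f"{str(c)[:width - 2]:>{width}}"
                                        for c in text.columns)
    lines = [header]
    for row in text.index:
        lines.append(f"{str(row):<22}"
                     + "".join(f"{text.loc[row, c]:>{width}}" for c in text.columns))
    lines.append("")
    lines.append("significance (two-tailed): * p<=0.05, ** p<=0.01, *** p<=0.001")
    return "\n".join(lines) + "\n"


def render_group_comparison(rows: list[GroupComparison], key: str) -> str:
    """Quartile table: mean (SD) with SNK letters per group, plus F and p."""
    header = (f"{'variable':<34}"
              + "".join(f"{g:>18}" for g in GROUP_LABELS)
              + f"{'F':>8}{'p':>8}")
    lines = [f"groups by {key}: Q1 = top 25%, Q4 = bottom 25%", header]
    for r in rows:
        cells = []
        for g in GROUP_LABELS:
            letters = r.letters[g]
            cells.append(f"{r.group_means[g]:.2f} ({r.group_sds[g]:.2f})"
                         f"{letters and ' ' + letters or '':<3}")
        lines.append(f"{r.variable:<34}" + "".join(f"{c:>18}" for c in cells)
                     + f"{r.f:>8.2f}{r.p:>8.3f}")
    lines.append("")
    lines.append("groups sharing a letter do not differ (SNK, p < 0.05)")
    return "\n".join(lines) + "\n"


def render_farm_panel(scorecards: list[ScoreCard],
                      kpis: pd.DataFrame | None = None) -> str:
    """Per-farm stacked view of the ten index scores (a text Figure-1).

    Each index contributes a band of '#' proportional to its score; the
    overall score and, when available, PWSY and medication cost are printed
    alongside.
    """
    lines = []
    kpi_by_farm = {}
    if kpis is not None and "farm_id" in kpis.columns:
        kpi_by_farm = kpis.set_index("farm_id").to_dict("index")
    for card in scorecards:
        bar = "".join("#" * int(round(s.points)) + "|" for s in card.index_scores)
        extra = ""
        k = kpi_by_farm.get(card.farm_id)
        if k:
            pwsy = k.get("pwsy")
            med = k.get("medication_cost_eur_per_piglet")
            if pwsy is not None and med is not None:
                extra = f"  PWSY {pwsy:6.2f}  med EUR {med:5.2f}"
        lines.append(f"{card.farm_id:<12} {_fmt(card.overall):>6}  {bar}{extra}")
    return "\n".join(lines) + "\n"
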