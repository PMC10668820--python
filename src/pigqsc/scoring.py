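"""Scoring engine: factor -> index -> farm.

A farm assessment is a set of checklist responses for the seven farm-level
indices plus, for each post-weaning room, responses for the three room-level
facility indices (temperature, ventilation, floor/density).  Each index score
is the weighted sum of its factor credits (0-10 points); room-level indices
take the arithmetic mean over rooms, every room counting equally; the overall
score is the plain sum of the ten index scores (0-100).

Strict mode (default) refuses to score an assessment with missing responses.
Lenient mode scores a missing factor as 0 points with a warning — the
conservative reading when every index is treated as a potential limiting
factor.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

from .errors import ContractError, MissingResponseError
from .schema import (
    CalculatorSchema,
    FactorDefinition,
    IndexDefinition,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FactorResponse",
    "RoomAssessment",
    "FarmAssessment",
    "IndexScore",
    "ScoreCard",
    "score_factor",
    "score_index",
    "score_room_index",
    "score_farm",
    "score_cohort",
    "perfect_assessment",
    "worst_assessment",
    "area_per_10kg",
    "response_prevalence",
]


@dataclass(slots=True)
class FactorResponse:
    """One checklist answer.

    ``value`` is a bool (binary), an option label (categorical) or a measured
    quantity in the factor's documented units (numeric_threshold).  ``missing``
    marks a factor that could not be observed on the visit.
    """

    factor_id: str
    value: bool | str | float | None = None
    missing: bool = False


@dataclass(slots=True)
class RoomAssessment:
    room_id: str
    responses: dict[str, FactorResponse]


@dataclass(slots=True)
class FarmAssessment:
    farm_id: str
    farm_responses: dict[str, FactorResponse]
    rooms: list[RoomAssessment]
    visit_date: _dt.date | None = None


@dataclass(slots=True)
class IndexScore:
    index_id: int
    name: str
    points: float
    per_factor_points: dict[str, float]
    per_room_points: dict[str, float] = field(default_factory=dict)


@dataclass(slots=True)
class ScoreCard:
    farm_id: str
    index_scores: list[IndexScore]
    overall: float

    def index_points(self) -> dict[int, float]:
        return {s.index_id: s.points for s in self.index_scores}


# ---------------------------------------------------------------------------
# helpers

def area_per_10kg(area_m2_per_pig: float, live_weight_kg: float) -> float:
    """Normalise a stocking-density observation to m2 per 10 kg live weight.

    E.g. 0.35 m2 available for a 30 kg pig -> 0.1167, which passes the
    >= 0.1 m2/10 kg requirement.
    """
    if live_weight_kg <= 0:
        raise ContractError(f"live weight must be positive, got {live_weight_kg}")
    return area_m2_per_pig / (live_weight_kg / 10.0)


def _ctx(farm_id: str | None, room_id: str | None) -> str:
    parts = []
    if farm_id is not None:
        parts.append(f"farm {farm_id!r}")
    if room_id is not None:
        parts.append(f"room {room_id!r}")
    return " ".join(parts) or "assessment"


# ---------------------------------------------------------------------------
# scoring operations

def score_factor(definition: FactorDefinition, response: FactorResponse | None,
                 *, strict: bool = True, farm_id: str | None = None,
                 room_id: str | None = None) -> float:
    """Points earned by one factor: weight x credit fraction of the answer."""
    if response is not None and response.factor_id != definition.id:
        raise ContractError(
            f"response for factor {response.factor_id!r} scored against "
            f"definition {definition.id!r}")
    if response is None or response.missing or response.value is None:
        if strict:
            raise MissingResponseError(
                f"missing response for factor {definition.id!r} in "
                f"{_ctx(farm_id, room_id)}")
        logger.warning("lenient mode: scoring missing factor %r as 0 points (%s)",
                       definition.id, _ctx(farm_id, room_id))
        return 0.0

    spec = definition.response
    value = response.value
    if spec.kind == "binary":
        if not isinstance(value, bool):
            raise ContractError(
                f"factor {definition.id!r} expects a yes/no answer, got "
                f"{value!r} ({_ctx(farm_id, room_id)})")
        return definition.weight if value else 0.0
    if spec.kind == "categorical":
        if not isinstance(value, str):
            raise ContractError(
                f"factor {definition.id!r} expects an option label from "
                f"{list(spec.labels)}, got {value!r} ({_ctx(farm_id, room_id)})")
        try:
            credit = spec.credit_for(value)
        except KeyError:
            raise ContractError(
                f"factor {definition.id!r}: unknown option {value!r} "
                f"(expected one of {list(spec.labels)}, {_ctx(farm_id, room_id)})"
            ) from None
        return definition.weight * credit
    # numeric_threshold — comparison is inclusive in either direction
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ContractError(
            f"factor {definition.id!r} expects a measured quantity "
            f"({spec.units or 'number'}), got {value!r} ({_ctx(farm_id, room_id)})")
    if value < 0:
        raise ContractError(
            f"factor {definition.id!r}: measured quantity must be non-negative, "
            f"got {value!r} ({_ctx(farm_id, room_id)})")
    if spec.direction == "ge":
        passed = value >= spec.threshold
    else:
        passed = value <= spec.threshold
    return definition.weight if passed else 0.0


def score_index(definition: IndexDefinition, responses: dict[str, FactorResponse],
                *, strict: bool = True, farm_id: str | None = None,
                room_id: str | None = None) -> IndexScore:
    """Sum the factor points of one index for one response set."""
    per_factor: dict[str, float] = {}
    for f in definition.factors:
        per_factor[f.id] = score_factor(f, responses.get(f.id), strict=strict,
                                        farm_id=farm_id, room_id=room_id)
    return IndexScore(index_id=definition.id, name=definition.name,
                      points=sum(per_factor.values()), per_factor_points=per_factor)


def score_room_index(definition: IndexDefinition, rooms: list[RoomAssessment],
                     *, strict: bool = True,
                     farm_id: str | None = None) -> IndexScore:
    """Score a room-level index: per-room sums, farm score = mean over rooms."""
    if definition.level != "room":
        raise ContractError(f"index {definition.id} is not room-level")
    if not rooms:
        raise ContractError(
            f"no rooms to score for index {definition.id} in {_ctx(farm_id, None)}")
    per_room: dict[str, float] = {}
    factor_sums = {f.id: 0.0 for f in definition.factors}
    for room in rooms:
        s = score_index(definition, room.responses, strict=strict,
                        farm_id=farm_id, room_id=room.room_id)
        per_room[room.room_id] = s.points
        for fid, pts in s.per_factor_points.items():
            factor_sums[fid] += pts
    n = len(rooms)
    return IndexScore(
        index_id=definition.id, name=definition.name,
        points=sum(per_room.values()) / n,
        per_factor_points={fid: tot / n for fid, tot in factor_sums.items()},
        per_room_points=per_room,
    )


def score_farm(assessment: FarmAssessment, schema: CalculatorSchema,
               *, strict: bool = True) -> ScoreCard:
    """Produce the full 10-index score card for one farm."""
    if len(assessment.rooms) != len({r.room_id for r in assessment.rooms}):
        raise ContractError(f"duplicate room ids in farm {assessment.farm_id!r}")
    scores: list[IndexScore] = []
    for ix in schema.indices:
        if ix.level == "farm":
            scores.append(score_index(ix, assessment.farm_responses, strict=strict,
                                      farm_id=assessment.farm_id))
        else:
            scores.append(score_room_index(ix, assessment.rooms, strict=strict,
                                           farm_id=assessment.farm_id))
    overall = sum(s.points for s in scores)
    logger.debug("scored farm %s: overall %.2f", assessment.farm_id, overall)
    return ScoreCard(farm_id=assessment.farm_id, index_scores=scores, overall=overall)


def score_cohort(assessments: list[FarmAssessment], schema: CalculatorSchema,
                 *, strict: bool = True) -> list[ScoreCard]:
    """Score a list of farms, preserving input order; farm ids must be unique."""
    seen: set[str] = set()
    for a in assessments:
        if a.farm_id in seen:
            raise ContractError(f"duplicate farm_id {a.farm_id!r} in cohort")
        seen.add(a.farm_id)
    return [score_farm(a, schema, strict=strict) for a in assessments]


# ---------------------------------------------------------------------------
# assessment construction

def _best_value(f: FactorDefinition):
    spec = f.response
    if spec.kind == "binary":
        return True
    if spec.kind == "categorical":
        return max(spec.options, key=lambda oc: oc[1])[0]
    # inclusive threshold: the pass mark itself earns full credit
    return float(spec.threshold)


def _worst_value(f: FactorDefinition):
    spec = f.response
    if spec.kind == "binary":
        return False
    if spec.kind == "categorical":
        return min(spec.options, key=lambda oc: oc[1])[0]
    if spec.direction == "ge":
        return 0.0 if spec.threshold > 0 else None
    return float(spec.threshold) * 2 + 1.0


def _build(schema: CalculatorSchema, farm_id: str, n_rooms: int, pick) -> FarmAssessment:
    farm_responses = {
        f.id: FactorResponse(f.id, pick(f))
        for ix in schema.farm_level_indices for f in ix.factors
    }
    room_factor_defs = [f for ix in schema.room_level_indices for f in ix.factors]
    rooms = [
        RoomAssessment(
            room_id=f"room{r + 1}",
            responses={f.id: FactorResponse(f.id, pick(f)) for f in room_factor_defs},
        )
        for r in range(n_rooms)
    ]
    return FarmAssessment(farm_id=farm_id, farm_responses=farm_responses, rooms=rooms)


def perfect_assessment(schema: CalculatorSchema, farm_id: str = "perfect",
                       n_rooms: int = 2) -> FarmAssessment:
    """An assessment answering every factor with the best-practice response."""
    return _build(schema, farm_id, n_rooms, _best_value)


def worst_assessment(schema: CalculatorSchema, farm_id: str = "worst",
                     n_rooms: int = 2) -> FarmAssessment:
    """An assessment answering every factor with the zero-credit response."""
    return _build(schema, farm_id, n_rooms, _worst_value)


def response_prevalence(assessments: list[FarmAssessment], factor_id: str,
                        predicate) -> float:
    """Fraction of farms whose response to ``factor_id`` satisfies ``predicate``.

    For room-level factors a farm counts if any of its rooms satisfies the
    predicate (e.g. "the farm has localized heating").
    """
    if not assessments:
        raise ContractError("empty cohort")
    hits = 0
    for a in assessments:
        resp = a.farm_responses.get(factor_id)
        if resp is not None:
            hits += bool(predicate(resp.value))
            continue
        room_values = [r.responses[factor_id].value for r in a.rooms
                       if factor_id in r.responses]
        if not room_values:
            raise ContractError(f"factor {factor_id!r} not answered by farm "
                                f"{a.farm_id!r}")
        hits += any(predicate(v) for v in room_values)
    return hits / len(assessments)
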