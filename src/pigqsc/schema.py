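"""Calculator schema: the declarative definition of the quick-scan calculator.

The calculator scores ten management themes ("indices") of a post-weaning pig
farm.  Each index is worth 10 points and is decomposed into 3-8 checklist
factors with point weights; a perfectly managed farm totals 100.  The schema
encodes that structure as data (a YAML document), so factor weights can be
recalibrated without touching code.

Three response kinds are supported:

``binary``
    presence/absence of a good practice (no = 0, yes = full weight).
``categorical``
    an ordered set of labelled options, each granting a fraction of the
    weight (credits must run from 0 to 1, non-decreasing).
``numeric_threshold``
    a measured quantity compared against a pass mark, e.g. drinker flow
    >= 1 L/min, >= 0.1 drinkers per piglet, or >= 0.1 m2 of floor per 10 kg
    live weight.  The comparison is inclusive.

Seven indices are answered once per farm; the three facility indices
(temperature, ventilation, floor/density) are answered per post-weaning room
and averaged by the scoring engine.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable

import yaml

from .errors import SchemaFormatError, SchemaValidationError

__all__ = [
    "ResponseSpec",
    "FactorDefinition",
    "IndexDefinition",
    "CalculatorSchema",
    "Violation",
    "ValidationReport",
    "load_schema",
    "loads_schema",
    "validate_schema",
    "default_schema",
    "write_schema",
    "dumps_schema",
]

INDEX_POINTS = 10.0
TOTAL_POINTS = 100.0
N_INDICES = 10
MIN_FACTORS = 3
MAX_FACTORS = 8
#: index ids evaluated per post-weaning room and averaged to the farm level
ROOM_LEVEL_INDEX_IDS = (8, 9, 10)

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True, slots=True)
class ResponseSpec:
    """How a factor's checklist answer maps to a credit fraction in [0, 1]."""

    kind: str  # binary | categorical | numeric_threshold
    options: tuple[tuple[str, float], ...] = ()  # (label, credit) for categorical
    threshold: float | None = None
    direction: str = "ge"  # ge | le, inclusive either way
    units: str = ""

    def credit_for(self, label: str) -> float:
        for opt, credit in self.options:
            if opt == label:
                return credit
        raise KeyError(label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(opt for opt, _ in self.options)


BINARY = ResponseSpec(kind="binary", options=(("no", 0.0), ("yes", 1.0)))


@dataclass(frozen=True, slots=True)
class FactorDefinition:
    """One checklist row: a management factor with its point weight."""

    id: str
    text: str
    weight: float
    response: ResponseSpec


@dataclass(frozen=True, slots=True)
class IndexDefinition:
    """One of the ten management themes, worth 10 points."""

    id: int
    name: str
    level: str  # farm | room
    factors: tuple[FactorDefinition, ...]

    @property
    def max_points(self) -> float:
        return sum(f.weight for f in self.factors)

    def factor(self, factor_id: str) -> FactorDefinition:
        for f in self.factors:
            if f.id == factor_id:
                return f
        raise KeyError(factor_id)


@dataclass(frozen=True, slots=True)
class CalculatorSchema:
    """The full calculator: exactly ten indices, 100 points in total."""

    version: str
    indices: tuple[IndexDefinition, ...]

    def index(self, index_id: int) -> IndexDefinition:
        for ix in self.indices:
            if ix.id == index_id:
                return ix
        raise KeyError(index_id)

    @property
    def farm_level_indices(self) -> tuple[IndexDefinition, ...]:
        return tuple(ix for ix in self.indices if ix.level == "farm")

    @property
    def room_level_indices(self) -> tuple[IndexDefinition, ...]:
        return tuple(ix for ix in self.indices if ix.level == "room")

    def all_factors(self) -> Iterable[tuple[IndexDefinition, FactorDefinition]]:
        for ix in self.indices:
            for f in ix.factors:
                yield ix, f


@dataclass(frozen=True, slots=True)
class Violation:
    """One invariant breach; ``index_id``/``factor_id`` locate it."""

    rule: str
    message: str
    index_id: int | None = None
    factor_id: str | None = None

    def __str__(self) -> str:
        where = ""
        if self.index_id is not None:
            where = f" [index {self.index_id}"
            if self.factor_id is not None:
                where += f", factor {self.factor_id!r}"
            where += "]"
        return f"{self.rule}: {self.message}{where}"


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...] = ()

    @property
    def valid(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff valid
        return self.valid

    def __str__(self) -> str:
        if self.valid:
            return "schema valid"
        return "\n".join(str(v) for v in self.violations)


# ---------------------------------------------------------------------------
# validation

def validate_schema(schema: CalculatorSchema) -> ValidationReport:
    """Check every schema invariant; violations are returned, never raised."""
    out: list[Violation] = []

    if len(schema.indices) != N_INDICES:
        out.append(Violation("index-count",
                             f"expected {N_INDICES} indices, found {len(schema.indices)}"))
    ids = [ix.id for ix in schema.indices]
    if len(set(ids)) != len(ids):
        out.append(Violation("index-ids-unique", f"duplicate index ids in {ids}"))
    if len(schema.indices) == N_INDICES and sorted(ids) != list(range(1, N_INDICES + 1)):
        out.append(Violation("index-ids-complete",
                             f"index ids must be 1..{N_INDICES}, found {sorted(ids)}"))

    for ix in schema.indices:
        if ix.level not in ("farm", "room"):
            out.append(Violation("level", f"level must be farm|room, got {ix.level!r}",
                                 ix.id))
        expected_level = "room" if ix.id in ROOM_LEVEL_INDEX_IDS else "farm"
        if ix.level in ("farm", "room") and ix.level != expected_level:
            out.append(Violation("room-level-indices",
                                 f"index {ix.id} must be level={expected_level!r}", ix.id))
        n = len(ix.factors)
        if not (MIN_FACTORS <= n <= MAX_FACTORS):
            out.append(Violation("factor-count",
                                 f"factor count {MIN_FACTORS}..{MAX_FACTORS}, found {n}",
                                 ix.id))
        fids = [f.id for f in ix.factors]
        if len(set(fids)) != len(fids):
            out.append(Violation("factor-ids-unique", f"duplicate factor ids {fids}", ix.id))
        total = ix.max_points
        if abs(total - INDEX_POINTS) > _WEIGHT_TOL:
            out.append(Violation("weight-sum",
                                 f"factor weights sum to {total:.4f}, expected "
                                 f"{INDEX_POINTS:g}", ix.id))
        for f in ix.factors:
            if not f.weight > 0:
                out.append(Violation("weight>0", f"weight must be > 0, got {f.weight}",
                                     ix.id, f.id))
            out.extend(_validate_response(f.response, ix.id, f.id))

    return ValidationReport(tuple(out))


def _validate_response(spec: ResponseSpec, index_id: int, factor_id: str) -> list[Violation]:
    out: list[Violation] = []
    if spec.kind not in ("binary", "categorical", "numeric_threshold"):
        out.append(Violation("response-kind", f"unknown kind {spec.kind!r}",
                             index_id, factor_id))
        return out
    if spec.kind in ("binary", "categorical"):
        credits = [c for _, c in spec.options]
        if not credits:
            out.append(Violation("options-nonempty", "no response options",
                                 index_id, factor_id))
            return out
        if any(c < 0 or c > 1 for c in credits):
            out.append(Violation("credit-range", f"credits outside [0,1]: {credits}",
                                 index_id, factor_id))
        if credits != sorted(credits):
            out.append(Violation("credit-monotone",
                                 f"credits must be non-decreasing in option order: "
                                 f"{credits}", index_id, factor_id))
        if credits and (credits[0] != 0.0 or credits[-1] != 1.0):
            out.append(Violation("credit-span", "credits must include 0 and 1",
                                 index_id, factor_id))
        if spec.kind == "binary" and len(credits) != 2:
            out.append(Violation("binary-two-options",
                                 f"binary factor needs exactly 2 options, found "
                                 f"{len(credits)}", index_id, factor_id))
    else:  # numeric_threshold
        if spec.threshold is None:
            out.append(Violation("threshold-required", "numeric_threshold needs a "
                                 "threshold value", index_id, factor_id))
        if spec.direction not in ("ge", "le"):
            out.append(Violation("threshold-direction",
                                 f"direction must be ge|le, got {spec.direction!r}",
                                 index_id, factor_id))
    return out


# ---------------------------------------------------------------------------
# parsing

_INDEX_KEYS = {"id", "name", "level", "factors"}
_FACTOR_KEYS = {"id", "text", "weight", "response"}
_RESPONSE_KEYS = {"kind", "options", "threshold", "direction", "units"}
_TOP_KEYS = {"version", "indices"}


def _require_mapping(node, where: str) -> dict:
    if not isinstance(node, dict):
        raise SchemaFormatError(f"{where}: expected a mapping, got {type(node).__name__}")
    return node


def _check_keys(node: dict, allowed: set[str], where: str) -> None:
    unknown = set(node) - allowed
    if unknown:
        raise SchemaFormatError(
            f"{where}: unknown field(s) {sorted(unknown)} (allowed: {sorted(allowed)})")


def _parse_response(node, where: str) -> ResponseSpec:
    if node is None:
        return BINARY
    node = _require_mapping(node, where)
    _check_keys(node, _RESPONSE_KEYS, where)
    kind = node.get("kind", "binary")
    if kind == "binary":
        return BINARY
    if kind == "categorical":
        raw = node.get("options")
        if not isinstance(raw, list):
            raise SchemaFormatError(f"{where}: categorical response needs an "
                                    f"'options' list")
        options = []
        for i, opt in enumerate(raw):
            opt = _require_mapping(opt, f"{where}.options[{i}]")
            _check_keys(opt, {"label", "credit"}, f"{where}.options[{i}]")
            try:
                options.append((str(opt["label"]), float(opt["credit"])))
            except KeyError as exc:
                raise SchemaFormatError(
                    f"{where}.options[{i}]: missing field {exc}") from exc
        return ResponseSpec(kind="categorical", options=tuple(options))
    if kind == "numeric_threshold":
        if "threshold" not in node:
            raise SchemaFormatError(f"{where}: numeric_threshold needs 'threshold'")
        return ResponseSpec(
            kind="numeric_threshold",
            threshold=float(node["threshold"]),
            direction=str(node.get("direction", "ge")),
            units=str(node.get("units", "")),
        )
    raise SchemaFormatError(f"{where}: unknown response kind {kind!r}")


def _parse_index(node, pos: int) -> IndexDefinition:
    where = f"indices[{pos}]"
    node = _require_mapping(node, where)
    _check_keys(node, _INDEX_KEYS, where)
    for key in ("id", "name", "factors"):
        if key not in node:
            raise SchemaFormatError(f"{where}: missing field {key!r}")
    index_id = int(node["id"])
    raw_factors = node["factors"]
    if not isinstance(raw_factors, list):
        raise SchemaFormatError(f"{where}.factors: expected a list")

    factors: list[tuple[str, str, float | None, ResponseSpec]] = []
    for j, fnode in enumerate(raw_factors):
        fwhere = f"{where}.factors[{j}]"
        fnode = _require_mapping(fnode, fwhere)
        _check_keys(fnode, _FACTOR_KEYS, fwhere)
        for key in ("id", "text"):
            if key not in fnode:
                raise SchemaFormatError(f"{fwhere}: missing field {key!r}")
        weight = fnode.get("weight")
        if weight is not None:
            try:
                weight = float(weight)
            except (TypeError, ValueError) as exc:
                raise SchemaFormatError(f"{fwhere}.weight: not a number "
                                        f"({fnode['weight']!r})") from exc
        response = _parse_response(fnode.get("response"), f"{fwhere}.response")
        factors.append((str(fnode["id"]), str(fnode["text"]), weight, response))

    # Factors without an explicit weight share the points left over after the
    # explicit ones, so a partial recalibration never breaks the 10-point sum.
    explicit = sum(w for _, _, w, _ in factors if w is not None)
    n_auto = sum(1 for _, _, w, _ in factors if w is None)
    auto = (INDEX_POINTS - explicit) / n_auto if n_auto else 0.0
    defs = tuple(
        FactorDefinition(id=fid, text=text, weight=(w if w is not None else auto),
                         response=resp)
        for fid, text, w, resp in factors
    )
    level = str(node.get("level", "room" if index_id in ROOM_LEVEL_INDEX_IDS else "farm"))
    return IndexDefinition(id=index_id, name=str(node["name"]), level=level, factors=defs)


def loads_schema(text: str) -> CalculatorSchema:
    """Parse a schema document from a YAML/JSON string and validate it."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise SchemaFormatError(f"schema does not parse{loc}: {exc}") from exc
    doc = _require_mapping(doc, "document")
    _check_keys(doc, _TOP_KEYS, "document")
    if "indices" not in doc:
        raise SchemaFormatError("document: missing field 'indices'")
    if not isinstance(doc["indices"], list):
        raise SchemaFormatError("document.indices: expected a list")
    schema = CalculatorSchema(
        version=str(doc.get("version", "0")),
        indices=tuple(_parse_index(node, i) for i, node in enumerate(doc["indices"])),
    )
    report = validate_schema(schema)
    if not report.valid:
        raise SchemaValidationError(report.violations)
    return schema


def load_schema(source) -> CalculatorSchema:
    """Load a schema from a path or an open text stream."""
    if hasattr(source, "read"):
        return loads_schema(source.read())
    with open(source, "r", encoding="utf-8") as fh:
        return loads_schema(fh.read())


# ---------------------------------------------------------------------------
# serialisation

def _response_to_dict(spec: ResponseSpec) -> dict | None:
    if spec.kind == "binary":
        return None
    if spec.kind == "categorical":
        return {"kind": "categorical",
                "options": [{"label": l, "credit": c} for l, c in spec.options]}
    return {"kind": "numeric_threshold", "threshold": spec.threshold,
            "direction": spec.direction, "units": spec.units}


def schema_to_dict(schema: CalculatorSchema) -> dict:
    indices = []
    for ix in schema.indices:
        factors = []
        for f in ix.factors:
            node: dict = {"id": f.id, "text": f.text, "weight": f.weight}
            resp = _response_to_dict(f.response)
            if resp is not None:
                node["response"] = resp
            factors.append(node)
        indices.append({"id": ix.id, "name": ix.name, "level": ix.level,
                        "factors": factors})
    return {"version": schema.version, "indices": indices}


def dumps_schema(schema: CalculatorSchema) -> str:
    return yaml.safe_dump(schema_to_dict(schema), sort_keys=False,
                          allow_unicode=True, width=100)


def write_schema(schema: CalculatorSchema, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_schema(schema))


def default_schema() -> CalculatorSchema:
    """The packaged default calculator definition (10 indices, 49 factors)."""
    text = (importlib.resources.files("pigqsc.data") / "default_schema.yaml").read_text(
        encoding="utf-8")
    return loads_schema(text)
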