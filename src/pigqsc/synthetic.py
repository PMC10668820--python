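"""Synthetic farm-cohort generator.

The study data behind the calculator are confidential, so end-to-end testing
and calibration run on simulated cohorts that reproduce the statistical
structure the analytics assume:

* each farm carries a latent management quality ``u ~ N(0, 1)``;
* every checklist factor is an ordinal item on that latent scale: the
  response crosses ordered logistic thresholds ``t = beta*u + eps``,
  ``eps ~ Logistic(0, 1)``, with the thresholds solved numerically so the
  marginal expected credit of each factor matches a configured target
  (defaults: the per-index mean scores observed in the field study, /10);
* room-level factors add a per-room disturbance shared across the room's
  factors (``v = u + sigma_room * w``), so rooms within a farm resemble each
  other more than rooms across farms;
* KPIs are coupled to the realized overall score S by the exact construction
  ``KPI = mu + sd * (rho * z + sqrt(1 - rho^2) * eps)`` with ``z`` the
  standardized score, so the population score-KPI correlation is the
  configured ``rho`` (defaults: the field study's overall-score
  correlations, e.g. 0.592 with PWSY and -0.414 with medication cost).

Everything is driven by one integer seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ContractError, DegenerateInputError
from .schema import CalculatorSchema, FactorDefinition, default_schema
from .scoring import (
    FactorResponse,
    FarmAssessment,
    RoomAssessment,
    ScoreCard,
    score_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "KpiCoupling",
    "GeneratorConfig",
    "SyntheticCohort",
    "default_generator_config",
    "generate_assessments",
    "couple_kpis",
    "generate_cohort",
    "expected_overall",
]

#: default marginal expected credit per index (index id -> mean score / 10),
#: taken from the field study's per-index cohort means
INDEX_CREDIT_TARGETS = {
    1: 0.687, 2: 0.598, 3: 0.511, 4: 0.481, 5: 0.574,
    6: 0.628, 7: 0.493, 8: 0.408, 9: 0.432, 10: 0.803,
}

#: factor-level overrides for practices with reported prevalences well away
#: from their index mean (near-zero incentive schemes, rare minimum-
#: ventilation programs)
FACTOR_CREDIT_OVERRIDES = {
    "minimum_ventilation": 0.13,
    "incentive_policy": 0.05,
}


@dataclass(frozen=True, slots=True)
class KpiCoupling:
    """Marginal mean/SD of one KPI and its target correlation with the score."""

    name: str
    mean: float
    sd: float
    rho: float
    lower: float = -np.inf
    upper: float = np.inf


#: marginals from the field cohort; rho from its overall-score correlation row
#: (KPIs outside that row are generated uncoupled)
DEFAULT_KPI_COUPLINGS = (
    KpiCoupling("n_sows", 704.30, 364.42, 0.0, lower=1.0),
    KpiCoupling("pwsy", 24.60, 3.20, 0.592, lower=0.0),
    KpiCoupling("pre_weaning_mortality_pct", 10.28, 4.37, 0.0, lower=0.0, upper=100.0),
    KpiCoupling("weaning_weight_kg", 5.67, 0.18, 0.0, lower=0.0),
    KpiCoupling("weaned_piglet_cost_eur", 24.69, 3.60, -0.182, lower=0.0),
    KpiCoupling("adg_g_per_d", 310.78, 38.71, 0.086, lower=0.0),
    KpiCoupling("fcr", 1.76, 0.16, -0.442, lower=0.0),
    KpiCoupling("medication_cost_eur_per_piglet", 5.69, 1.44, -0.414, lower=0.0),
    KpiCoupling("post_weaning_mortality_pct", 3.46, 1.47, -0.437, lower=0.0, upper=100.0),
    KpiCoupling("total_cost_eur_per_piglet", 45.14, 4.70, -0.435, lower=0.0),
    KpiCoupling("cost_per_kg_lw_eur", 2.33, 0.31, -0.228, lower=0.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All the knobs of the cohort generator.

    Defaults emulate the field study's conditions: 23 farms, a discretized
    Normal(10.52, 5.48) number of post-weaning rooms (min 3), factor credit
    targets matching the observed per-index means, and KPI couplings from the
    observed overall-score correlation row.
    """

    n_farms: int = 23
    seed: int = 0
    rooms_mean: float = 10.52
    rooms_sd: float = 5.48
    rooms_min: int = 3
    latent_slope: float = 1.0       # beta: discrimination of every factor
    room_sigma: float = 0.5         # SD of the per-room latent disturbance
    categorical_spread: float = 1.0  # gap between adjacent ordinal thresholds
    credit_targets: dict[str, float] | None = None  # factor_id -> E[credit]
    kpi_couplings: tuple[KpiCoupling, ...] = DEFAULT_KPI_COUPLINGS
    couple_to: str = "score"        # "score" (exact calibration) | "latent"
    truncate: bool = True

    def validate(self) -> None:
        if self.n_farms < 1:
            raise ContractError(f"n_farms must be >= 1, got {self.n_farms}")
        if self.rooms_sd <= 0 or self.rooms_min < 1:
            raise ContractError("rooms_sd must be > 0 and rooms_min >= 1")
        if self.room_sigma < 0 or self.categorical_spread <= 0:
            raise ContractError("room_sigma must be >= 0 and "
                                "categorical_spread > 0")
        if self.couple_to not in ("score", "latent"):
            raise ContractError(f"couple_to must be 'score' or 'latent', got "
                                f"{self.couple_to!r}")
        for c in self.kpi_couplings:
            if abs(c.rho) > 1:
                raise ContractError(f"KPI {c.name!r}: |rho| must be <= 1, got {c.rho}")
            if c.sd <= 0:
                raise ContractError(f"KPI {c.name!r}: sd must be > 0, got {c.sd}")
        if self.credit_targets is not None:
            for fid, t in self.credit_targets.items():
                if not 0 < t < 1:
                    raise ContractError(f"credit target for {fid!r} must be in "
                                        f"(0,1), got {t}")


def default_generator_config(n_farms: int = 23, seed: int = 0,
                             **overrides) -> GeneratorConfig:
    return GeneratorConfig(n_farms=n_farms, seed=seed, **overrides)


def _credit_targets(config: GeneratorConfig,
                    schema: CalculatorSchema) -> dict[str, float]:
    if config.credit_targets is not None:
        return dict(config.credit_targets)
    targets = {}
    for ix, f in schema.all_factors():
        targets[f.id] = FACTOR_CREDIT_OVERRIDES.get(
            f.id, INDEX_CREDIT_TARGETS.get(ix.id, 0.5))
    return targets


# ---------------------------------------------------------------------------
# ordinal item model

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def _mean_sigmoid(scale: float, tau: float) -> float:
    """E_u[ logistic(scale*u - tau) ] for u ~ N(0,1), by Gauss-Hermite."""
    z = np.sqrt(2.0) * _GH_NODES * scale - tau
    return float(np.sum(_GH_WEIGHTS / (1.0 + np.exp(-z))) / np.sqrt(np.pi))


def _factor_credits(f: FactorDefinition) -> np.ndarray:
    spec = f.response
    if spec.kind in ("binary", "categorical"):
        return np.array([c for _, c in spec.options], dtype=float)
    return np.array([0.0, 1.0])  # numeric threshold: fail / pass


def _solve_thresholds(credits: np.ndarray, target: float, scale: float,
                      spread: float) -> np.ndarray:
    """Ordered thresholds tau_1..tau_{K-1} such that E[credit] = target.

    Thresholds are an equally spaced ladder centred at c; only the centre is
    solved.  E[credit] = sum_j (c_j - c_{j-1}) * P(t > tau_j) with
    t = scale*u + Logistic(0,1) noise.
    """
    k = credits.size
    offsets = spread * (np.arange(1, k) - k / 2.0)
    gaps = np.diff(credits)
    target = float(np.clip(target, 1e-4, 1 - 1e-4))

    def expected(center: float) -> float:
        return float(sum(g * _mean_sigmoid(scale, center + o)
                         for g, o in zip(gaps, offsets)))

    center = brentq(lambda c: expected(c) - target, -60.0, 60.0, xtol=1e-10)
    return center + offsets


def expected_overall(config: GeneratorConfig,
                     schema: CalculatorSchema | None = None) -> float:
    """Closed-form expectation of the overall score under the generator.

    By construction each factor's marginal expected credit equals its
    configured target, so E[S] = sum_f weight_f * target_f (room averaging
    does not change the expectation).
    """
    schema = schema or default_schema()
    targets = _credit_targets(config, schema)
    return float(sum(f.weight * targets[f.id] for _, f in schema.all_factors()))


# ---------------------------------------------------------------------------
# assessment generation

def _draw_option_indices(taus: np.ndarray, latent: np.ndarray,
                         beta: float, rng: np.random.Generator) -> np.ndarray:
    t = beta * latent + rng.logistic(size=latent.size)
    return (t[:, None] > taus[None, :]).sum(axis=1)


def _numeric_value(passed: np.ndarray, threshold: float, direction: str,
                   rng: np.random.Generator) -> np.ndarray:
    """A plausible measured quantity consistent with each pass/fail draw."""
    u = rng.uniform(size=passed.size)
    if direction == "ge":
        return np.where(passed, threshold * (1.0 + 0.5 * u), threshold * 0.99 * u)
    return np.where(passed, threshold * u, threshold * (1.01 + 0.5 * u))


def _generate(config: GeneratorConfig, schema: CalculatorSchema,
              rng: np.random.Generator):
    """Core generator; returns (assessments, latent_quality)."""
    config.validate()
    n = config.n_farms
    beta = config.latent_slope
    targets = _credit_targets(config, schema)

    u = rng.standard_normal(n)
    n_rooms = np.maximum(
        np.rint(rng.normal(config.rooms_mean, config.rooms_sd, size=n)).astype(int),
        config.rooms_min)
    total_rooms = int(n_rooms.sum())
    farm_of_room = np.repeat(np.arange(n), n_rooms)
    # per-room disturbance, shared by all factors of the room
    v = u[farm_of_room] + config.room_sigma * rng.standard_normal(total_rooms)
    room_scale = beta * float(np.hypot(1.0, config.room_sigma))

    farm_values: dict[str, np.ndarray] = {}
    room_values: dict[str, np.ndarray] = {}
    for ix in schema.indices:
        room_level = ix.level == "room"
        latent = v if room_level else u
        scale = room_scale if room_level else beta
        for f in ix.factors:
            credits = _factor_credits(f)
            taus = _solve_thresholds(credits, targets[f.id], scale,
                                     config.categorical_spread)
            idx = _draw_option_indices(taus, latent, beta, rng)
            spec = f.response
            if spec.kind == "binary":
                values = idx.astype(bool)
            elif spec.kind == "categorical":
                labels = np.array(spec.labels, dtype=object)
                values = labels[idx]
            else:
                values = _numeric_value(idx.astype(bool), float(spec.threshold),
                                        spec.direction, rng)
            (room_values if room_level else farm_values)[f.id] = values

    width = max(3, len(str(n)))
    room_offsets = np.concatenate(([0], np.cumsum(n_rooms)))
    room_factor_ids = [f.id for ix in schema.room_level_indices for f in ix.factors]
    assessments: list[FarmAssessment] = []
    for i in range(n):
        farm_id = f"farm{i + 1:0{width}d}"
        farm_responses = {
            fid: FactorResponse(fid, vals[i].item() if hasattr(vals[i], "item")
                                else vals[i])
            for fid, vals in farm_values.items()
        }
        rooms = []
        for j, r in enumerate(range(room_offsets[i], room_offsets[i + 1])):
            responses = {}
            for fid in room_factor_ids:
                val = room_values[fid][r]
                responses[fid] = FactorResponse(fid, val.item()
                                                if hasattr(val, "item") else val)
            rooms.append(RoomAssessment(room_id=f"room{j + 1}", responses=responses))
        assessments.append(FarmAssessment(farm_id=farm_id,
                                          farm_responses=farm_responses,
                                          rooms=rooms))
    return assessments, u


def generate_assessments(config: GeneratorConfig,
                         schema: CalculatorSchema | None = None,
                         seed: int | None = None) -> list[FarmAssessment]:
    """Draw one cohort of farm assessments from the latent-quality model."""
    schema = schema or default_schema()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    assessments, _ = _generate(config, schema, rng)
    return assessments


# ---------------------------------------------------------------------------
# KPI coupling

def couple_kpis(scorecards, config: GeneratorConfig,
                seed: int | None = None,
                rng: np.random.Generator | None = None,
                farm_ids=None) -> pd.DataFrame:
    """Draw the KPI table, calibrated against the overall scores.

    ``scorecards`` may be a list of ScoreCard objects or a plain vector of
    overall scores.  For each KPI with target correlation rho the draw is
    ``mu + sd * (rho * z + sqrt(1-rho^2) * eps)`` with ``z`` the standardized
    score vector, so the targeted correlation holds exactly in population and
    up to Monte-Carlo noise in-sample.  Truncation to the KPI's physical
    range is applied afterwards and logged.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    if scorecards is not None and len(scorecards) and isinstance(scorecards[0], ScoreCard):
        scores = np.array([c.overall for c in scorecards], dtype=float)
        if farm_ids is None:
            farm_ids = [c.farm_id for c in scorecards]
    else:
        scores = np.asarray(scorecards, dtype=float)
    if scores.size == 0:
        raise ContractError("no score cards to couple KPIs to")
    sd = scores.std()
    if sd == 0:
        raise DegenerateInputError("overall scores have zero variance; cannot "
                                   "standardize for KPI coupling")
    z = (scores - scores.mean()) / sd

    data: dict[str, np.ndarray] = {}
    if farm_ids is not None:
        data["farm_id"] = np.asarray(farm_ids, dtype=object)
    for c in config.kpi_couplings:
        eps = rng.standard_normal(scores.size)
        kpi = c.mean + c.sd * (c.rho * z + np.sqrt(1.0 - c.rho ** 2) * eps)
        if config.truncate:
            clipped = int(np.sum((kpi < c.lower) | (kpi > c.upper)))
            if clipped:
                logger.info("KPI %s: clipped %d/%d values to [%g, %g]",
                            c.name, clipped, kpi.size, c.lower, c.upper)
            kpi = np.clip(kpi, c.lower, c.upper)
        data[c.name] = kpi
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# full cohort

@dataclass(frozen=True)
class SyntheticCohort:
    assessments: list[FarmAssessment]
    scorecards: list[ScoreCard]
    kpis: pd.DataFrame
    provenance: dict


def generate_cohort(config: GeneratorConfig,
                    schema: CalculatorSchema | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Assessments + score cards + coupled KPI table, one seed end to end."""
    schema = schema or default_schema()
    use_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(use_seed)
    rng_assess, rng_kpi = (np.random.default_rng(s) for s in ss.spawn(2))
    assessments, u = _generate(config, schema, rng_assess)
    scorecards = score_cohort(assessments, schema)
    if config.couple_to == "score":
        driver = [c.overall for c in scorecards]
    else:
        # latent mode: correlations with the realized score attenuate by
        # corr(score, u) < 1
        driver = u
    kpis = couple_kpis(np.asarray(driver, dtype=float), config, rng=rng_kpi,
                       farm_ids=[c.farm_id for c in scorecards])
    provenance = {"seed": use_seed, "config": asdict(config),
                  "schema_version": schema.version}
    return SyntheticCohort(assessments=assessments, scorecards=scorecards,
                           kpis=kpis, provenance=provenance)
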