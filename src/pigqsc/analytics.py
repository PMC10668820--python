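"""Benchmarking analytics for a farm cohort.

The unit of analysis is the cohort table: one row per farm, carrying the ten
index scores, the overall score, and the production/health KPIs collected
over one year (PWSY, mortality rates, weaning weight, costs, ADG, FCR).

Provided here:

* descriptive benchmarking (mean, SD, min, max, quartiles) with two
  percentile definitions — the SPSS weighted-average ("haverage", position
  (n+1)p) and plain linear interpolation;
* Pearson correlations with two-tailed p-values and significance stars
  (* p<=0.05, ** p<=0.01, *** p<=0.001);
* quartile benchmarking: top 25% (Q1) vs middle 50% (Q2Q3) vs bottom 25%
  (Q4) of farms ranked on a KPI;
* one-way ANOVA followed by the Student–Newman–Keuls (SNK) stepwise
  multiple-range test, reported as compact letters (groups sharing a letter
  are not significantly different);
* a Shapiro–Wilk normality check (advisory).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "SCORE_COLUMNS",
    "OVERALL_COLUMN",
    "KPI_COLUMNS",
    "TABLE_KPI_COLUMNS",
    "CorrelationCell",
    "CorrelationTable",
    "QuartileGrouping",
    "GroupComparison",
    "stars_for_p",
    "describe",
    "pearson_with_p",
    "correlation_table",
    "assign_quartile_groups",
    "one_way_anova",
    "snk_posthoc",
    "check_normality",
    "compare_groups",
]

#: index-score columns of the cohort table, in calculator order 1..10
SCORE_COLUMNS = (
    "pre_weaning",
    "batch_management",
    "biosecurity",
    "water_management",
    "feed_management",
    "health_program",
    "stockmen_training",
    "temperature",
    "ventilation",
    "floor_density",
)
OVERALL_COLUMN = "overall"

#: every KPI column the cohort table may carry, with units
KPI_COLUMNS = (
    "n_sows",                       # mean number of reproductive sows
    "pwsy",                         # piglets weaned per sow per year
    "pre_weaning_mortality_pct",    # %
    "weaning_weight_kg",            # kg
    "weaned_piglet_cost_eur",       # EUR per weaned piglet
    "adg_g_per_d",                  # post-weaning average daily gain, g/day
    "fcr",                          # post-weaning feed conversion ratio
    "medication_cost_eur_per_piglet",  # EUR, post-weaning veterinary medication
    "post_weaning_mortality_pct",   # %
    "total_cost_eur_per_piglet",    # EUR, post-weaning feed+husbandry+medication
    "cost_per_kg_lw_eur",           # EUR per kg live weight produced
)

#: the eight KPIs of the score-vs-KPI correlation table, in column order
TABLE_KPI_COLUMNS = (
    "pwsy",
    "weaned_piglet_cost_eur",
    "adg_g_per_d",
    "fcr",
    "medication_cost_eur_per_piglet",
    "post_weaning_mortality_pct",
    "total_cost_eur_per_piglet",
    "cost_per_kg_lw_eur",
)

ALPHA_DEFAULT = 0.05


def stars_for_p(p: float) -> str:
    """Significance stars; thresholds are inclusive."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# descriptive benchmarking

_PCTL_METHODS = {"haverage": "weibull", "linear": "linear"}


def describe(cohort: pd.DataFrame, variables=None, *,
             percentile_method: str = "haverage") -> pd.DataFrame:
    """Mean/SD/min/max/P25/P50/P75 per variable, one row each.

    SD is the sample (n-1) standard deviation.  ``haverage`` is the SPSS
    weighted-average percentile (position (n+1)p); ``linear`` interpolates
    between order statistics at position 1+(n-1)p.
    """
    if percentile_method not in _PCTL_METHODS:
        raise ContractError(f"unknown percentile method {percentile_method!r}; "
                            f"choose from {sorted(_PCTL_METHODS)}")
    np_method = _PCTL_METHODS[percentile_method]
    if variables is None:
        variables = [c for c in cohort.columns
                     if pd.api.types.is_numeric_dtype(cohort[c])]
    rows = []
    for var in variables:
        if var not in cohort.columns:
            raise ContractError(f"unknown variable {var!r} in cohort table")
        x = pd.to_numeric(cohort[var], errors="coerce").dropna().to_numpy(float)
        if x.size == 0:
            raise ContractError(f"variable {var!r} has no non-missing values")
        p25, p50, p75 = np.percentile(x, [25, 50, 75], method=np_method)
        rows.append({
            "variable": var,
            "n": int(x.size),
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "p25": float(p25),
            "p50": float(p50),
            "p75": float(p75),
        })
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# correlation

@dataclass(frozen=True, slots=True)
class CorrelationCell:
    r: float
    p: float
    n: int
    stars: str

    def __str__(self) -> str:
        return f"{self.r:.3f}{' ' + self.stars if self.stars else ''}"


def pearson_with_p(x, y) -> CorrelationCell:
    """Product-moment correlation with a two-tailed p-value.

    The p-value is the classical t-transform test: t = r sqrt((n-2)/(1-r^2))
    on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError(f"x and y must be equal-length vectors, got shapes "
                            f"{x.shape} and {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ContractError(f"need n >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationCell(r=float(r), p=float(p), n=int(n), stars=stars_for_p(float(p)))


@dataclass(frozen=True)
class CorrelationTable:
    """Score-vs-KPI correlation matrix with per-cell p-values and stars."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame
    degenerate: tuple[tuple[str, str], ...] = ()

    def cell(self, row: str, col: str) -> CorrelationCell:
        return CorrelationCell(r=float(self.r.loc[row, col]),
                               p=float(self.p.loc[row, col]),
                               n=int(self.n.loc[row, col]),
                               stars=str(self.stars.loc[row, col]))

    def to_text_frame(self) -> pd.DataFrame:
        """Cells rendered as '0.592 **' strings (3 decimals + stars)."""
        out = self.r.round(3).astype(object).copy()
        for row in out.index:
            for col in out.columns:
                if (row, col) in self.degenerate:
                    out.loc[row, col] = "n/a"
                else:
                    out.loc[row, col] = str(self.cell(row, col))
        return out


def correlation_table(cohort: pd.DataFrame, score_columns=None,
                      kpi_columns=None) -> CorrelationTable:
    """Pearson r between every score column and every KPI column.

    Default layout: 11 rows (10 indices + overall) x 8 KPI columns.  Missing
    KPI cells are handled by pairwise-complete deletion; per-cell n is
    recorded.  Degenerate cells (constant column) are flagged and left NaN
    rather than failing the whole table.
    """
    score_columns = list(score_columns or (*SCORE_COLUMNS, OVERALL_COLUMN))
    kpi_columns = list(kpi_columns or TABLE_KPI_COLUMNS)
    for col in (*score_columns, *kpi_columns):
        if col not in cohort.columns:
            raise ContractError(f"column {col!r} not in cohort table")
    shape = (len(score_columns), len(kpi_columns))
    r = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    n = np.zeros(shape, dtype=int)
    s = np.full(shape, "", dtype=object)
    degenerate: list[tuple[str, str]] = []
    for i, sc in enumerate(score_columns):
        for j, kc in enumerate(kpi_columns):
            try:
                cell = pearson_with_p(cohort[sc], cohort[kc])
            except (DegenerateInputError, ContractError) as exc:
                logger.warning("correlation (%s, %s) degenerate: %s", sc, kc, exc)
                degenerate.append((sc, kc))
                continue
            r[i, j], p[i, j], n[i, j], s[i, j] = cell.r, cell.p, cell.n, cell.stars
    idx = pd.Index(score_columns, name="score")
    cols = pd.Index(kpi_columns, name="kpi")
    return CorrelationTable(
        r=pd.DataFrame(r, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        n=pd.DataFrame(n, index=idx, columns=cols),
        stars=pd.DataFrame(s, index=idx, columns=cols),
        degenerate=tuple(degenerate),
    )


# ---------------------------------------------------------------------------
# quartile benchmarking

GROUP_LABELS = ("Q1", "Q2Q3", "Q4")


@dataclass(frozen=True)
class QuartileGrouping:
    """Partition of the cohort into best 25% / middle 50% / worst 25%."""

    key: str
    direction: str  # "high": Q1 = highest key values; "low": Q1 = lowest
    membership: pd.Series  # farm_id -> Q1 | Q2Q3 | Q4

    def farms(self, label: str) -> list:
        return list(self.membership.index[self.membership == label])

    @property
    def sizes(self) -> dict[str, int]:
        return {g: int((self.membership == g).sum()) for g in GROUP_LABELS}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def assign_quartile_groups(cohort: pd.DataFrame, key: str,
                           direction: str = "high",
                           id_column: str = "farm_id") -> QuartileGrouping:
    """Rank farms on ``key`` and split them round(n/4) / rest / round(n/4).

    ``direction="high"`` puts the highest key values in Q1 (e.g. most
    productive farms by PWSY, or highest medication spenders).  Ties are
    broken by stable input order, with a warning when tied values straddle a
    group boundary.
    """
    if direction not in ("high", "low"):
        raise ContractError(f"direction must be 'high' or 'low', got {direction!r}")
    if key not in cohort.columns:
        raise ContractError(f"column {key!r} not in cohort table")
    ids = (cohort[id_column] if id_column in cohort.columns
           else pd.Series(cohort.index, index=cohort.index))
    values = pd.to_numeric(cohort[key], errors="raise").to_numpy(float)
    n = values.size
    if n < 4:
        raise ContractError(f"need n >= 4 farms to form quartile groups, got {n}")
    sort_key = -values if direction == "high" else values
    order = np.argsort(sort_key, kind="stable")  # stable: ties keep input order
    n_extreme = _round_half_up(n / 4)
    sorted_vals = values[order]
    for cut in (n_extreme, n - n_extreme):
        if sorted_vals[cut - 1] == sorted_vals[cut]:
            logger.warning("tied %s values at a quartile boundary; ties broken "
                           "by input order", key)
    labels = np.empty(n, dtype=object)
    labels[order[:n_extreme]] = "Q1"
    labels[order[n_extreme:n - n_extreme]] = "Q2Q3"
    labels[order[n - n_extreme:]] = "Q4"
    membership = pd.Series(labels, index=pd.Index(ids, name=id_column), name="group")
    return QuartileGrouping(key=key, direction=direction, membership=membership)


# ---------------------------------------------------------------------------
# ANOVA + SNK

@lru_cache(maxsize=512)
def _q_crit(alpha: float, span: int, dfw: int) -> float:
    """Upper-alpha studentized-range quantile q(alpha; span, dfw), memoized
    because scipy's inversion is expensive and SNK reuses few distinct values."""
    return float(stats.studentized_range.ppf(1 - alpha, span, dfw))


def _anova_decomposition(groups):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ContractError(f"need >= 2 groups, got {len(arrays)}")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ContractError(f"group {i} has n={g.size}; need n >= 2 per group")
        if not np.all(np.isfinite(g)):
            raise ContractError(f"group {i} contains non-finite values")
    ns = np.array([g.size for g in arrays])
    means = np.array([g.mean() for g in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(arrays, means)))
    df_between = len(arrays) - 1
    df_within = int(ns.sum()) - len(arrays)
    return arrays, ns, means, ss_between, ss_within, df_between, df_within


def one_way_anova(groups) -> tuple[float, float]:
    """Fixed-effects one-way ANOVA: F = MS_between / MS_within and its p."""
    _, _, _, ssb, ssw, dfb, dfw = _anova_decomposition(groups)
    if ssw == 0.0:
        raise DegenerateInputError("zero within-group variance: F undefined")
    ms_between = ssb / dfb
    ms_within = ssw / dfw
    f = ms_between / ms_within
    p = float(stats.f.sf(f, dfb, dfw))
    return float(f), p


@dataclass(frozen=True)
class SNKResult:
    """Outcome of the Student–Newman–Keuls multiple-range test.

    ``letters[i]`` belongs to input group ``i``; groups sharing any letter
    were not separated at level alpha.  ``significant_pairs`` holds (i, j)
    input-index pairs declared different.
    """

    letters: list[str]
    significant_pairs: frozenset[tuple[int, int]]
    ms_within: float
    df_within: int
    alpha: float

    def different(self, i: int, j: int) -> bool:
        return tuple(sorted((i, j))) in self.significant_pairs


def snk_posthoc(groups, alpha: float = ALPHA_DEFAULT) -> SNKResult:
    """Student–Newman–Keuls stepwise range test with a compact letter display.

    Group means are sorted in descending order; a span of p adjacent means is
    tested with the studentized-range critical value q(alpha, p, df_within)
    and standard error sqrt(MS_within / n_h), n_h the harmonic mean of the
    group sizes in the span.  Once a span is found homogeneous, no pair
    inside it is tested again (the step-down protection that distinguishes
    SNK from per-pair range tests).
    """
    if not 0 < alpha < 1:
        raise ContractError(f"alpha must be in (0,1), got {alpha}")
    arrays, ns, means, _, ssw, _, dfw = _anova_decomposition(groups)
    if ssw == 0.0:
        raise DegenerateInputError("zero within-group variance: SNK undefined")
    msw = ssw / dfw
    k = len(arrays)
    order = np.argsort(-means, kind="stable")  # descending means
    sorted_means = means[order]
    sorted_ns = ns[order]

    homogeneous: list[tuple[int, int]] = []  # inclusive windows in sorted order

    def covered(a: int, b: int) -> bool:
        return any(lo <= a and b <= hi for lo, hi in homogeneous)

    for span in range(k, 1, -1):
        q_critical = _q_crit(alpha, span, dfw)
        for start in range(0, k - span + 1):
            end = start + span - 1
            if covered(start, end):
                continue
            n_h = span / np.sum(1.0 / sorted_ns[start:end + 1])
            se = math.sqrt(msw / n_h)
            q_obs = (sorted_means[start] - sorted_means[end]) / se
            if q_obs < q_critical:
                homogeneous.append((start, end))

    significant: set[tuple[int, int]] = set()
    for a in range(k):
        for b in range(a + 1, k):
            if not covered(a, b):
                significant.add(tuple(sorted((int(order[a]), int(order[b])))))

    # compact letter display: one letter per maximal homogeneous interval,
    # singletons for groups not covered by any interval
    intervals = [iv for iv in homogeneous
                 if not any(iv != o and o[0] <= iv[0] and iv[1] <= o[1]
                            for o in homogeneous)]
    for pos in range(k):
        if not any(lo <= pos <= hi for lo, hi in intervals):
            intervals.append((pos, pos))
    intervals.sort()
    letters_sorted = ["" for _ in range(k)]
    for letter_i, (lo, hi) in enumerate(intervals):
        letter = chr(ord("a") + letter_i)
        for pos in range(lo, hi + 1):
            letters_sorted[pos] += letter
    letters = ["" for _ in range(k)]
    for pos, gi in enumerate(order):
        letters[int(gi)] = letters_sorted[pos]
    return SNKResult(letters=letters, significant_pairs=frozenset(significant),
                     ms_within=float(msw), df_within=int(dfw), alpha=alpha)


def check_normality(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p.  Advisory: callers log, they do not gate on it."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ContractError(f"need a vector with n >= 3, got shape {x.shape}")
    if np.ptp(x) == 0:
        raise ContractError("constant vector: normality test undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# group-comparison tables

@dataclass(frozen=True)
class GroupComparison:
    """One row of a quartile-comparison table."""

    variable: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    f: float
    p: float
    letters: dict[str, str]
    shapiro_p: float | None = None


def compare_groups(cohort: pd.DataFrame, grouping: QuartileGrouping,
                   variables, alpha: float = ALPHA_DEFAULT,
                   id_column: str = "farm_id") -> list[GroupComparison]:
    """ANOVA + SNK letters for each variable across the quartile groups.

    Normality of each variable is checked (Shapiro–Wilk) and logged; the
    parametric pipeline runs regardless, mirroring an advisory pre-check.
    """
    ids = (cohort[id_column] if id_column in cohort.columns
           else pd.Series(cohort.index, index=cohort.index))
    labels = grouping.membership.reindex(pd.Index(ids)).to_numpy()
    if pd.isna(labels).any():
        raise ContractError("grouping does not cover every farm in the cohort")
    out: list[GroupComparison] = []
    for var in variables:
        if var not in cohort.columns:
            raise ContractError(f"column {var!r} not in cohort table")
        x = pd.to_numeric(cohort[var], errors="raise").to_numpy(float)
        try:
            _, shapiro_p = check_normality(x)
            if shapiro_p <= alpha:
                logger.warning("variable %s departs from normality "
                               "(Shapiro p=%.3g)", var, shapiro_p)
        except ContractError:
            shapiro_p = None
        groups = [x[labels == g] for g in GROUP_LABELS]
        f, p = one_way_anova(groups)
        snk = snk_posthoc(groups, alpha=alpha)
        out.append(GroupComparison(
            variable=var,
            group_means={g: float(gv.mean()) for g, gv in zip(GROUP_LABELS, groups)},
            group_sds={g: float(gv.std(ddof=1)) for g, gv in zip(GROUP_LABELS, groups)},
            group_ns={g: int(gv.size) for g, gv in zip(GROUP_LABELS, groups)},
            f=float(f), p=float(p),
            letters=dict(zip(GROUP_LABELS, snk.letters)),
            shapiro_p=shapiro_p,
        ))
    return out
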