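# Methods

## The scoring model

The calculator is a two-level weighted checklist. Every index holds 3–8
factors; factor *f* of index *i* has weight w_{if} > 0 points with
Σ_f w_{if} = 10 exactly, giving a 0–10 index score and a 0–100 farm total.
Responses map to credit fractions:

* **binary** — absence/presence of a good practice: credit 0 or 1;
* **categorical** — ordered options with credits that must be
  non-decreasing and span [0, 1]. Where the checklist names "three possible
  categories" without grading them, the default is equal spacing
  (0, ½, 1). Both the option labels and credits are schema data and can be
  overridden without code changes;
* **numeric_threshold** — a measured quantity against a pass mark, compared
  *inclusively* in the printed direction (flow ≥ 1 L/min, drinkers/piglet
  ≥ 0.1, floor area ≥ 0.1 m² per 10 kg live weight). A helper
  (`area_per_10kg`) normalises an area-per-pig observation at a given live
  weight to the per-10 kg scale; other units are taken as documented in the
  schema and not converted at score time.

Indices 8–10 (temperature, ventilation, floor/density) are answered per
post-weaning room; the farm's index score is the unweighted arithmetic mean
over rooms — rooms count equally regardless of size, since no room-size
weighting is part of the protocol. Scores are carried at full floating
precision and rounded to two decimals only when rendered.

**Default factor weights.** The packaged schema splits each index's 10
points equally over its factors (10/n per factor, e.g. 1.25 for each of the
eight biosecurity factors). Equal split is the natural uninformative prior
for a checklist of this kind and is consistent with the granularity of
scores such a calculator produces in the field (index scores falling on
multiples of 10/n); a panel-calibrated weight table can be dropped into the
YAML file — any factor left without a `weight:` key absorbs an equal share
of the index's remaining points, so partial recalibration is safe.

**Missing responses.** Strict mode (default) raises an error naming the
farm, room and factor. Lenient mode scores a missing factor as 0 points with
a warning: under the limiting-factor reading of the indices, "not observed"
is treated no better than "absent". Field protocols for unobservable items
vary; the two modes bracket the reasonable choices.

## Benchmarking analytics

* **Descriptives** — mean, sample (n−1) SD, min, max, P25/P50/P75. Two
  percentile definitions are supported because benchmark reports produced
  with different statistics packages disagree on small n: `haverage`
  (default), the SPSS weighted-average definition at position (n+1)p, and
  `linear` interpolation at position 1+(n−1)p. Both are hand-verified in the
  tests on a 4-point dataset.
* **Correlation** — product-moment r with the two-tailed t-transform
  p-value (t = r√((n−2)/(1−r²)), n−2 df; delegated to
  `scipy.stats.pearsonr`, which implements exactly this test). Stars:
  `*` p ≤ 0.05, `**` p ≤ 0.01, `***` p ≤ 0.001, inclusive at the
  boundaries. The standard table layout is 11 score rows (10 indices +
  overall) × 8 KPI columns. Missing KPI cells use pairwise-complete
  deletion with per-cell n recorded; a constant column flags its cells as
  degenerate rather than failing the table. No multiple-testing correction
  is applied across the 88 cells — the table is descriptive benchmarking,
  not confirmatory inference.
* **Quartile benchmarking** — farms ranked on a KPI; the extreme groups
  take round-half-up(n/4) farms each (n=23 → 6/11/6), the middle 50%
  (Q2+Q3) forms one group. `direction="high"` puts the highest values in
  Q1 (most productive farms; highest medication spenders). Ties are broken
  by stable input order with a logged warning.
* **ANOVA + SNK** — one-way fixed-effects ANOVA from explicit sums of
  squares (cross-checked against `scipy.stats.f_oneway` in the tests; the
  decomposition is computed in-package because the SNK step needs
  MS_within and its df). The Student–Newman–Keuls test sorts group means
  descending and tests each contiguous span of p means with the
  studentized-range quantile q(α, p, df_within) and standard error
  √(MS_within/n_h), n_h the harmonic mean of the span's group sizes
  (the standard extension for unequal groups). A span found homogeneous is
  never re-entered (step-down protection). Results are rendered as compact
  letters — one letter per maximal homogeneous span, highest mean = "a";
  groups sharing any letter are not separated at α. For k = 2 the SNK
  decision coincides with the pooled t-test (q = √2·|t|); on the widest
  span it coincides with Tukey's HSD, and SNK rejections are always a
  superset of Tukey's — both identities are exercised as test oracles.
  Under the complete null the family-wise error equals the level of the
  widest-span test; a 5,000-replicate seeded simulation (k=3, n=6) checks
  FWER ≤ α + Monte-Carlo tolerance.
* **Normality** — Shapiro–Wilk, advisory only: departures are logged, the
  parametric pipeline is never blocked, matching the role of a normality
  pre-check in a benchmarking report.

## The synthetic cohort generator

The generator exists because cohort records of this kind (farm audits +
yearly KPIs) are confidential; it produces data with the statistical
structure the analytics assume, not copies of any real farms.

* **Latent trait.** Farm i carries management quality u_i ~ N(0,1). Every
  checklist factor is an ordinal item: response level = number of ordered
  thresholds crossed by t = β·u_i + ε, ε ~ Logistic(0,1). The thresholds
  form an equally spaced ladder (spacing 1.0 on the logistic scale) whose
  centre is solved by Brent's method + 64-node Gauss–Hermite quadrature so
  that the *marginal expected credit* of the factor equals its configured
  target. Hence E[overall] = Σ_f w_f·target_f in closed form, which the
  tests verify by Monte Carlo (n = 5,000 farms, ±2 points).
* **Credit targets.** Defaults are the per-index mean scores observed when
  the calculator was field-tested on a 23-farm cohort, divided by 10
  (0.687, 0.598, 0.511, 0.481, 0.574, 0.628, 0.493, 0.408, 0.432, 0.803
  for indices 1–10), with factor-level overrides for two practices reported
  as much rarer than their index average: minimum-ventilation programs
  (0.13) and performance incentives (0.05 — reported prevalence is zero,
  but a zero target has no finite logit threshold, so a near-zero rate is
  used). The discrimination β = 1 for every factor and a per-room
  disturbance σ_room = 0.5 (rooms share their farm's quality but differ
  consistently from each other) were fixed once as field-plausible values;
  β controls how strongly farms polarise, and the β→∞ limit (bimodal scores
  at 0/100) and β=0 limit (independent items at base rates) are both
  tested. Room count per farm: discretized N(10.52, 5.48), floored at 3 —
  the field cohort's marginal.
* **KPIs.** For each KPI with target correlation ρ, marginal mean μ and SD
  σ: KPI_i = μ + σ(ρ·z_i + √(1−ρ²)·ε_i), z the standardized overall score,
  ε_i ~ N(0,1) — so the score–KPI correlation is ρ by construction
  (exactly in population; to Monte-Carlo accuracy in-sample, |r−ρ| < 0.015
  at n = 50,000 in the tests). Defaults: ρ = 0.592 (PWSY), −0.182 (weaned
  piglet cost), 0.086 (ADG), −0.442 (FCR), −0.414 (medication cost),
  −0.437 (post-weaning mortality), −0.435 (total cost), −0.228 (cost/kg);
  marginals per the field cohort (e.g. PWSY 24.60 ± 3.20). KPIs outside
  the validated correlation row (sow count, pre-weaning mortality, weaning
  weight) are generated uncoupled. Values are clipped to their physical
  range (mortality ≥ 0, costs > 0) with a logged count; marginal
  mean/SD fidelity is tested with truncation off.
* **Coupling mode.** Coupling to the *realized score* makes calibration
  exact and is the default. `couple_to="latent"` couples to u instead,
  which is mechanistically more realistic but attenuates the observable
  correlation by corr(S, u) < 1; the attenuation is demonstrated in a
  test. Cross-KPI dependence arises only through the score — pairwise
  KPI–KPI correlations are not independently targeted. This is a known
  fidelity limit.
* **Determinism.** One integer seed drives everything through
  `numpy.random.SeedSequence` spawning; identical (config, seed) reproduce
  cohorts bit-for-bit, asserted on serialized output.

**What passing tests do and do not show.** The generator reproduces the
marginal index-score levels, the room-count distribution and the score–KPI
correlation structure of a real audit cohort; it does *not* reproduce
cross-factor dependence beyond the single latent trait (real farms violate
unidimensionality), KPI–KPI partial correlations, temporal drift, or
assessor disagreement. Green analytics tests therefore certify the
statistical machinery, not any empirical claim about real farms.

## Numerical choices

* Index weight sums validated to 1e-9; overall-sum decomposition asserted
  to 1e-9 in tests.
* Threshold comparisons inclusive (≥ / ≤) — boundary observations pass.
* Quartile rounding: half-up (floor(n/4 + 0.5)), avoiding banker's-rounding
  surprises at n ≡ 2 (mod 4).
* Studentized-range quantiles are memoized (scipy's inversion costs ~0.1 s
  per call; SNK re-uses few distinct (α, p, df) triples).
* Degenerate inputs raise typed errors rather than returning NaN: constant
  vectors in correlation/normality, zero within-group variance in
  ANOVA/SNK, zero score variance in KPI coupling.
* Ordinal threshold solver clips credit targets to [1e-4, 1−1e-4] and
  solves the ladder centre on [−60, 60] (logistic scale), ample for any
  representable target.

## Problem sizes in the checks

The acceptance script uses a 20,000-farm cohort (a few seconds of CPU) for
correlation recovery — large enough that Monte-Carlo noise on r is ≈ 0.005,
well inside the ±0.02 acceptance band. Unit tests use 23-farm (study-scale)
cohorts for shape/contract checks and 3,000–50,000 draws for calibration
checks, chosen so the whole suite runs in well under a minute.

## Known limitations

* Factor weights and categorical gradings default to equal splits; a
  panel-calibrated weight table would change individual index scores
  (though not the 0–100 scale or any invariant).
* The health-program index treats PRRS status as a single binary condition;
  biosecurity does not distinguish internal from external measures; water
  quality credits the act of analysing water, not the analysis results —
  deliberate simplicity inherited from the quick-scan design.
* No disease-outbreak dynamics: under a severe outbreak the score–KPI
  relationship the generator encodes would not hold.
* The analytics are descriptive benchmarking; no causal interpretation of
  score–KPI correlations is licensed.
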