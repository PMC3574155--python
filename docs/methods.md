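# Methods

`clustercea` implements a trial-based cost-effectiveness analysis for
cluster-randomised trials (CRTs), built around the comparison of an intensive
lifestyle-counselling arm with usual antenatal care in women at risk of
gestational diabetes. This note documents the models, the estimators, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Costing model

Each woman's societal cost is a sum of component costs over pregnancy up to
the last hospital day of mother and newborn, in 2009 euros:

* outpatient care: primary-care visits, specialist visits, diabetes-nurse and
  dietician hours, each `units × unit price`;
* two routine oral glucose tolerance tests per woman (overridable per record);
* one 2.5-month insulin course when insulin was used;
* inpatient days before/after the delivery stay at the hospital per-day price;
* patient daily charges (€30/day): uncapped for the mother's delivery stay,
  capped at 7 days for the newborn's stay;
* a delivery cost to the municipality by mode of delivery (vaginal,
  instrumental, elective/emergency caesarean) — these prices are not published
  unit costs and must be supplied in the config; the packaged defaults are
  illustrative placeholders used by the simulator;
* a neonatal municipality cost per day, applied only when the newborn's stay
  carries an ICD diagnosis (rooming-in care is inside the mother's delivery
  price);
* productivity losses: self-reported absence days × a daily salary cost
  (default €189/day; a salary overhead multiplier is exposed in the config and
  defaults to 1, because €189 is the operative published rate);
* the intervention's own delivery cost, intervention arm only: supplemental
  public-health-nurse time (2.1 h × €56) plus a per-person physiotherapist
  contribution (€23), about €141 per woman, scaled by a scenario multiplier
  (1 base, 2 in the doubled-cost sensitivity scenario).

Direct costs are the total minus productivity and intervention components.
All arithmetic is unrounded internally; euro rounding (half away from zero)
happens only at report rendering, as do the one-decimal quadrant shares and
the two-decimal per-gram ICERs.

## Effect measures

Three effects are analysed, each benefit-signed so that a positive
incremental effect is a health gain:

* **birth weight** (g): analysed as grams *avoided* in a macrosomia-risk
  population, so ΔE = mean(usual care) − mean(intervention);
* **15D utility change**: follow-up minus baseline index from the
  15-dimension HRQoL instrument; ΔE = mean(intervention) − mean(usual care);
* **VAS change** (cm on a 0–10 scale), same orientation as 15D.

The 15D index is an additive valuation `1 − Σ_d w_d (1 − v_d(level_d))` with
non-negative weights summing to one and per-dimension level values decreasing
from 1 (level 1) — so full health scores exactly 1. The licensed Finnish
tariff is not shipped; the valuation model is a config input, and
`ValuationModel15D.equal_weights()` provides a synthetic equal-weight linear
model (weights 1/15, values 1, .75, .5, .25, 0) for testing and simulation.

**Missing 15D dimensions.** At each timepoint: profiles with more than six
missing dimensions are excluded from 15D analyses, never imputed. Profiles
with one to six missing dimensions are completed by OLS regression of the
missing dimension's level *value* on the level values of the dimensions the
woman did answer plus age, education (ordinal 1–3), BMI and marital status
(binary), fitted over complete cases with arms pooled. The unstandardised
prediction is clipped to the dimension's value range and converted back to a
fractional level. Imputation is idempotent. Analysis sets are therefore
outcome-specific; for the cost–effect bootstrap the analysis set is the
intersection of women with cost data and with that outcome, so the
(cost, effect) pairing stays aligned.

## Two-stage bootstrap with shrinkage correction

Women within a maternity clinic are correlated, so the ordinary bootstrap
understates uncertainty. Uncertainty in (ΔC, ΔE) is estimated by a
non-parametric two-stage bootstrap (TSB): within each arm, resample clusters
first, then individuals within the drawn clusters, using

1. **shrunken cluster means** `ȳ + c(ȳ_j − ȳ)`, and
2. **standardised residuals** `r_ij = (y_ij − ȳ_j)·√(n_j/(n_j−1))`
   (a singleton cluster has residual 0),

computed per arm and per variable. One replicate draws, for each arm, M
clusters with replacement; each drawn cluster j contributes its own original
size n_j (this is the modification that accommodates unbalanced clusters) and
n_j residuals drawn with replacement from that same cluster; synthetic values
are shrunken mean + residual. The cost and effect draws share the same cluster
and residual indices, which is what preserves the cost–effect correlation in
the replicate pairs. Arm means of the synthetic samples give one replicate
(ΔC, ΔE); R replicates (default 5,000) are generated from per-replicate
substreams spawned from one root seed, so the stream is bit-reproducible and
extending R never perturbs earlier replicates.

**Shrinkage factor.** The raw cluster means over-disperse relative to the
between-cluster variance component (each carries within noise σ²_W/n_j), and
resampling M values through an empirical distribution with denominator M
loses a further (M−1)/M. The factor used here calibrates both at once:

    c² = σ̂²_B / ( (1/M) Σ_j (ȳ_j − ȳ)² ),  clamped to [0, 1],

with σ̂²_B = (MSB − MSW)/n₀ the one-way ANOVA between-cluster variance
component. The variance of one draw from the shrunken means then equals
σ̂²_B, which is exactly the between-cluster contribution a real cluster mean
carries. Degenerate inputs: SS_B = 0 gives c = 0 (with a warning); SS_W = 0
with SS_B > 0 gives c = 1. The residual scaling √(n_j/(n_j−1)) makes the mean
of squared residuals within a cluster equal its unbiased within-variance, so
with-replacement residual draws reproduce σ̂²_W. Calibration is verified
against the analytic two-level standard error √(σ²_B/M + σ²_W/(M·b̄)): the
TSB SE matches within a few percent, where the one-stage i.i.d. bootstrap
understates it by ~50% at high ICC.

**Confidence intervals.** 95% intervals for ΔC and ΔE use the bias-corrected
and accelerated (BCa) percentile method: bias constant
z₀ = Φ⁻¹((#{replicate < observed} + ½#{=})/R), acceleration â from the
jackknife skewness formula with **leave-one-cluster-out** estimates (the
cluster is the independence unit in a CRT), adjusted percentile points mapped
through the empirical replicate distribution. If all replicates coincide the
interval collapses to the observed value with a warning. The implementation
is cross-checked against `scipy.stats.bootstrap`'s independent BCa on i.i.d.
data.

**Known small-sample limitation.** With only 7 unbalanced clusters per arm,
percentile-type intervals behave like z- rather than t-intervals at roughly
12 effective degrees of freedom, and the ANOVA σ̂²_B is zero-truncated in a
sizeable share of arms at ICC ≈ 0.03. Measured over repeated synthetic trials
at the default study conditions, 95% BCa intervals for ΔC cover the truth
roughly 89–94% of the time depending on the Monte-Carlo block — near, and
sometimes below, the lower edge of the nominal level; coverage is solidly
nominal when the number of clusters per arm is doubled (≈95% at 14 per arm in
our diagnostics). This is a property of the method at this design size, not
of the implementation; the shrinkage calibration above already removes the
bulk of the deficit (a raw sum-of-squares shrinkage variant covers only
≈86%).

## Cost-effectiveness summaries

* **ICER** = ΔC/ΔE on the benefit-signed scale; ΔE = 0 yields an explicit
  "undefined" result rather than an infinity.
* **Plane quadrants**: NE requires strictly positive ΔE and ΔC; boundary ties
  (probability ~0 for continuous data) fall south/west, making the four
  counts an exact partition of R.
* **CEAC(λ)** = #{λ·ΔE − ΔC ≥ 0}/R over a willingness-to-pay grid; default
  grids are 0–50 €/g (birth weight), 0–200,000 €/15D unit, 0–10,000 €/cm
  (VAS), 200 points, configurable.
* **Scenarios**: `base`; `doubled_intervention` (multiplier 2 — identical
  effect replicate streams at the same seed, costs shifted by exactly one
  per-person intervention cost); `subgroup` (the intervention arm replaced by
  its adherent women — weight gain within limits AND (>800 MET-min/week of
  physical activity OR ≥3 of 5 dietary aims) — versus the full usual-care
  arm).

## Synthetic-data generator

The generator emulates the trial's structure with known ground truth: 7
clusters per arm with unbalanced sizes (Dirichlet-weighted, totals 219/180),
gamma-distributed total costs (arm means/SDs €7,763/4,511 and €6,994/4,326;
log-normal available), normal birth weight (3,521±545 / 3,636±500 g), small
negative 15D and VAS changes (−0.045/−0.052 ± 0.06; −0.32/−0.56 ± 1.21/1.13),
latent-scale intracluster correlations (defaults 0.02–0.03, within the
0.01–0.05 range typical of these outcomes), an individual-level cost–birth
weight coupling (ρ = 0.2), follow-up 15D missingness (11.8% fully missing,
2.3% partially missing with 1–6 dimensions, VAS missing with the full-missing
questionnaires, no one missing at both timepoints), ~0.3% missing birth
weight, and an adherent fraction of 55/219 in the intervention arm.

Service-use counts are back-solved from each drawn total cost: categorical
components (delivery mode, insulin, ICD neonatal care) are drawn first and
degraded if the drawn cost cannot carry them, then visit counts, absence
days, hospital days and extra stay days absorb the remainder in units of
their prices. The reconstruction is exact to the finest granularity (the €30
daily charge); a drawn cost below the minimal fixed components is clamped
with a warning. Consequently the *total* cost distribution is faithful while
per-component use patterns are not calibrated — the cost table rendered from
synthetic data will not match published component means, only the totals and
their contrasts. 15D profiles are built to score to the drawn utility index
under the configured valuation model (within one level step), and the VAS
pair is shifted jointly into [0, 10] so the change is preserved exactly.

What passing tests show: unbiased recovery of ΔC, ΔE and ICC; correct
resampling calibration; counting identities; qualitative NE-dominance. What
they cannot show: robustness to real-data features the generator omits —
informative missingness, registry/questionnaire discordance, skewed or
heaped service-use counts per component, cluster-level confounding, and
recruitment attrition.

## Numerical and design choices

* Missing tokens on input: empty field or `NA`; `NA` on output.
* Counts are integers; 15D levels are stored as floats so imputed fractional
  levels survive a round trip.
* ANOVA ICC estimates are clamped to [0, 1); the shrinkage factor to [0, 1].
* The BCa z₀ proportion is clamped to [1/(R+1), R/(R+1)] to keep it finite.
* Imputation requires more complete cases than predictors and errors
  otherwise, suggesting covariate reduction.
* Where registry and questionnaire sources could disagree, precedence is the
  caller's decision: the reader validates but never silently reconciles.

## Problem sizes used in tests

The test suite scales Monte-Carlo studies to keep a full run inside a few
minutes of CPU: variance calibration averages 60 datasets at R = 5,000;
interval coverage uses 500 generated trials at R = 1,000; parameter recovery
200 trials; null-case symmetry 100 trials at R = 200; the qualitative check
12 trials at R = 800. The acceptance script uses slightly smaller versions of
the same studies (reported in its output under `n`).
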