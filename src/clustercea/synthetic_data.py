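"""Synthetic cluster-randomised trial generator with known ground truth.

The generator emulates the statistical structure the pipeline assumes: two
arms (219 vs 180 women by default), seven maternity-clinic clusters per arm
with unbalanced sizes, right-skewed total costs, approximately normal birth
weight, small negative 15D and VAS changes, within-cluster correlation,
cost-effect correlation, and the observed pattern of 15D follow-up
missingness.  Service-use counts are back-solved so that
:func:`clustercea.costing.total_cost` reproduces each woman's drawn total cost
to within the finest component granularity (the 30-euro daily charge);
per-component use patterns are *not* calibrated to the source tables, only
the totals are.

Every dataset is reproducible from its seed, and a :class:`GroundTruth`
sidecar records the true incremental cost and effects so pipeline estimates
can be checked for bias and interval coverage.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import yaml

from .costing import total_cost
from .outcomes import ValuationModel15D
from .trial_io import (
    DELIVERY_MODES,
    INTERVENTION,
    N_DIMENSIONS,
    ParticipantRecord,
    TrialDataError,
    TrialDataset,
    USUAL_CARE,
    UnitCostTable,
)


def default_unit_costs() -> UnitCostTable:
    """Published unit prices plus illustrative (synthetic) delivery/neonatal prices.

    Delivery municipality costs by mode and the neonatal per-day price are not
    published; the values here are plausible 2009-level placeholders used by
    the simulator and examples, and should be replaced with local prices for
    any real analysis.
    """
    return UnitCostTable(
        delivery_mode_prices={"vaginal": 1500.0, "instrumental": 2000.0,
                              "elective_caesarean": 2500.0,
                              "emergency_caesarean": 3000.0},
        neonatal_day=440.0,
    )


@dataclass
class GeneratorParams:
    """Study conditions for one synthetic trial (defaults follow the source trial).

    Tuple-valued fields are (intervention, usual_care).  Costs are total 2009
    euros per woman; birth weight in grams; 15D change in index units; VAS
    change in cm.  ``icc_*`` are intracluster correlations on the latent
    scale; ``rho_cost_effect`` couples each woman's cost and birth-weight
    noise.
    """

    clusters_per_arm: int = 7
    n_per_arm: Tuple[int, int] = (219, 180)
    cost_mean: Tuple[float, float] = (7763.0, 6994.0)
    cost_sd: Tuple[float, float] = (4511.0, 4326.0)
    cost_family: str = "gamma"              # or "lognormal"
    bw_mean: Tuple[float, float] = (3521.0, 3636.0)
    bw_sd: Tuple[float, float] = (545.0, 500.0)
    d15_change_mean: Tuple[float, float] = (-0.045, -0.052)
    d15_change_sd: Tuple[float, float] = (0.06, 0.06)
    vas_change_mean: Tuple[float, float] = (-0.32, -0.56)
    vas_change_sd: Tuple[float, float] = (1.21, 1.13)
    d15_baseline_index_mean: float = 0.93
    d15_baseline_index_sd: float = 0.035
    vas_baseline_mean: float = 8.0
    vas_baseline_sd: float = 1.2
    icc_cost: float = 0.03
    icc_bw: float = 0.03
    icc_d15: float = 0.02
    icc_vas: float = 0.02
    rho_cost_effect: float = 0.2
    missing_full_15d: float = 0.118          # whole follow-up questionnaire missing
    missing_partial_15d: float = 0.023       # 1-6 follow-up dimensions missing
    missing_partial_baseline: float = 0.015
    bw_missing_rate: float = 0.003
    adherent_fraction: float = 55.0 / 219.0
    insulin_rate: float = 0.035
    neonatal_icd_rate: float = 0.08
    delivery_mode_probs: Tuple[float, ...] = (0.78, 0.06, 0.08, 0.08)
    seed: int = 0
    unit_costs: Optional[UnitCostTable] = None
    valuation_model: Optional[ValuationModel15D] = None

    def __post_init__(self):
        for name in ("icc_cost", "icc_bw", "icc_d15", "icc_vas"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise TrialDataError(f"{name} must be in [0, 1), got {v}")
        if not (-1.0 <= self.rho_cost_effect <= 1.0):
            raise TrialDataError("rho_cost_effect must be in [-1, 1]")
        for name in ("missing_full_15d", "missing_partial_15d",
                     "missing_partial_baseline", "bw_missing_rate",
                     "adherent_fraction", "insulin_rate", "neonatal_icd_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise TrialDataError(f"{name} must be a rate in [0, 1], got {v}")
        if any(s <= 0 for s in self.cost_sd + self.bw_sd):
            raise TrialDataError("SDs must be > 0")
        if self.clusters_per_arm < 2:
            raise TrialDataError("need at least 2 clusters per arm")


@dataclass
class GroundTruth:
    """True population quantities behind one generated trial."""

    delta_cost: float                      # intervention - usual care, euros
    delta_effect: dict                     # benefit-signed, per outcome
    icc: dict
    rho_cost_effect: float
    seed: int

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _cluster_sizes(total: int, m: int, rng) -> np.ndarray:
    """Unbalanced cluster sizes summing to ``total`` (each at least 5)."""
    props = rng.dirichlet(np.full(m, 4.0))
    sizes = np.floor(props * total).astype(int)
    while sizes.sum() < total:
        sizes[rng.integers(0, m)] += 1
    while sizes.min() < 5:
        sizes[np.argmax(sizes)] -= 1
        sizes[np.argmin(sizes)] += 1
    return sizes


def _two_level(mu, sd, icc, u_cluster, z_individual):
    """mu + sd * (sqrt(icc) u_j + sqrt(1-icc) z_i)."""
    return mu + sd * (np.sqrt(icc) * u_cluster + np.sqrt(1.0 - icc) * z_individual)


def _cost_from_normal(z: float, mean: float, sd: float, family: str) -> float:
    """Map a standard-normal latent to a right-skewed cost (quantile transform)."""
    from scipy import stats
    u = stats.norm.cdf(z)
    u = min(max(u, 1e-12), 1.0 - 1e-12)
    if family == "gamma":
        k = (mean / sd) ** 2
        theta = sd ** 2 / mean
        return float(stats.gamma.ppf(u, a=k, scale=theta))
    if family == "lognormal":
        s2 = np.log(1.0 + (sd / mean) ** 2)
        return float(stats.lognorm.ppf(u, s=np.sqrt(s2), scale=mean * np.exp(-s2 / 2)))
    raise TrialDataError(f"unknown cost family {family!r}")


# back-solve allocation: (field, unit price key, cap) in allocation order; the
# leftover below one 30-euro delivery-stay day is discarded
def _allocate_services(remainder: float, table: UnitCostTable) -> dict:
    alloc = {}
    steps = (
        ("visits_primary", table.primary_visit, 25),
        ("absence_days", table.absence_day, 60),
        ("hospital_days_pre_post", table.hospital_day, 12),
        ("visits_specialist", table.specialist_visit, 8),
        ("visits_diabetes_nurse", table.diabetes_nurse_hour, 5),
        ("extra_delivery_days", table.inpatient_daily_charge, 40),
    )
    r = remainder
    for name, price, cap in steps:
        k = min(int(r // price), cap) if price > 0 else 0
        alloc[name] = k
        r -= k * price
    return alloc


def _profile_for_index(target: float, model: ValuationModel15D, rng) -> list:
    """A 15D level profile whose index is as close as possible to ``target``."""
    levels = [1] * N_DIMENSIONS
    current = 1.0
    active = list(range(N_DIMENSIONS))
    while active:
        d = active[rng.integers(0, len(active))]
        if levels[d] >= 5:
            active.remove(d)
            continue
        step = model.weights[d] * (model.level_values[d][levels[d] - 1]
                                   - model.level_values[d][levels[d]])
        if current - target >= step / 2.0:
            levels[d] += 1
            current -= step
        else:
            active.remove(d)
    return [float(l) for l in levels]


def generate_trial(params: GeneratorParams,
                   seed: Optional[int] = None):
    """Generate one synthetic trial; returns ``(TrialDataset, GroundTruth)``."""
    table = params.unit_costs or default_unit_costs()
    model = params.valuation_model or ValuationModel15D.equal_weights()
    if table.delivery_mode_prices is None or table.neonatal_day is None:
        raise TrialDataError("generator needs delivery-mode and neonatal prices")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    records = []
    clamped = 0
    for a, (arm, prefix) in enumerate(((INTERVENTION, "I"), (USUAL_CARE, "U"))):
        m = params.clusters_per_arm
        sizes = _cluster_sizes(params.n_per_arm[a], m, rng)
        u_cost = rng.standard_normal(m)
        u_bw = rng.standard_normal(m)
        u_d15 = rng.standard_normal(m)
        u_vas = rng.standard_normal(m)
        pid = 0
        for j in range(m):
            for _ in range(sizes[j]):
                pid += 1
                # cost and birth-weight individual noise share a latent term
                z = rng.standard_normal(2)
                rho = params.rho_cost_effect
                z_cost = z[0]
                z_bw = rho * z[0] + np.sqrt(1.0 - rho ** 2) * z[1]
                cost_latent = _two_level(0.0, 1.0, params.icc_cost, u_cost[j], z_cost)
                drawn_cost = _cost_from_normal(cost_latent, params.cost_mean[a],
                                               params.cost_sd[a], params.cost_family)
                bw = _two_level(params.bw_mean[a], params.bw_sd[a], params.icc_bw,
                                u_bw[j], z_bw)
                d15_change = _two_level(params.d15_change_mean[a], params.d15_change_sd[a],
                                        params.icc_d15, u_d15[j], rng.standard_normal())
                vas_change = _two_level(params.vas_change_mean[a], params.vas_change_sd[a],
                                        params.icc_vas, u_vas[j], rng.standard_normal())

                mode = DELIVERY_MODES[rng.choice(4, p=params.delivery_mode_probs)]
                uses_insulin = rng.random() < params.insulin_rate
                neonatal_icd = rng.random() < params.neonatal_icd_rate
                neonatal_days = int(rng.integers(1, 8)) if neonatal_icd \
                    else int(1 + min(rng.poisson(2), 6))
                base_fixed = 2 * table.ogtt_test + 1 * table.inpatient_daily_charge
                if arm == INTERVENTION:
                    base_fixed += (table.intervention_nurse_hours * table.nurse_hour
                                   + table.physio_contribution) * table.scenario_multiplier_intervention

                def _fixed(mode, uses_insulin, neonatal_icd, neonatal_days):
                    return (base_fixed
                            + table.delivery_mode_prices[mode]
                            + min(neonatal_days, 7) * table.inpatient_daily_charge
                            + (table.insulin_course if uses_insulin else 0.0)
                            + (neonatal_days * table.neonatal_day if neonatal_icd else 0.0))

                # a cheap pregnancy cannot carry an expensive categorical
                # profile: degrade ICD care, insulin, delivery mode and the
                # neonatal stay before clamping (correlates severity with
                # cost, as in real data)
                if drawn_cost < _fixed(mode, uses_insulin, neonatal_icd, neonatal_days):
                    neonatal_icd = False
                if drawn_cost < _fixed(mode, uses_insulin, neonatal_icd, neonatal_days):
                    uses_insulin = False
                if drawn_cost < _fixed(mode, uses_insulin, neonatal_icd, neonatal_days):
                    mode = "vaginal"
                if drawn_cost < _fixed(mode, uses_insulin, neonatal_icd, neonatal_days):
                    neonatal_days = 0
                remainder = drawn_cost - _fixed(mode, uses_insulin, neonatal_icd, neonatal_days)
                if remainder < 0:
                    clamped += 1
                    remainder = 0.0
                alloc = _allocate_services(remainder, table)

                # 15D profiles matching the drawn baseline index and change
                idx_base = float(np.clip(rng.normal(params.d15_baseline_index_mean,
                                                    params.d15_baseline_index_sd), 0.55, 1.0))
                idx_follow = float(np.clip(idx_base + d15_change, 0.35, 1.0))
                d15_b = _profile_for_index(idx_base, model, rng)
                d15_f = _profile_for_index(idx_follow, model, rng)
                # shift the VAS pair jointly into [0, 10] so the change is
                # preserved exactly (one-sided clipping would bias the arms
                # differentially)
                vas_b = rng.normal(params.vas_baseline_mean, params.vas_baseline_sd)
                vas_f = vas_b + vas_change
                hi = max(vas_b, vas_f)
                if hi > 10.0:
                    vas_b, vas_f = vas_b - (hi - 10.0), vas_f - (hi - 10.0)
                lo = min(vas_b, vas_f)
                if lo < 0.0:
                    vas_b, vas_f = vas_b - lo, vas_f - lo
                vas_b = float(np.clip(np.round(vas_b, 1), 0.0, 10.0))
                vas_f = float(np.clip(np.round(vas_f, 1), 0.0, 10.0))

                # follow-up questionnaire missingness (15D and VAS together)
                u_miss = rng.random()
                vas_b_out, vas_f_out = vas_b, vas_f
                if u_miss < params.missing_full_15d:
                    d15_f = None
                    vas_f_out = None
                elif u_miss < params.missing_full_15d + params.missing_partial_15d:
                    k = int(rng.integers(1, 7))
                    for d in rng.choice(N_DIMENSIONS, size=k, replace=False):
                        d15_f[d] = None
                elif rng.random() < params.missing_partial_baseline:
                    # baseline partials never coincide with follow-up missingness
                    k = int(rng.integers(1, 7))
                    for d in rng.choice(N_DIMENSIONS, size=k, replace=False):
                        d15_b[d] = None

                bw_out = None if rng.random() < params.bw_missing_rate \
                    else float(np.round(max(bw, 300.0)))

                adherent = (arm == INTERVENTION) and rng.random() < params.adherent_fraction
                if adherent:
                    if rng.random() < 0.5:
                        met = float(rng.uniform(850.0, 2000.0))
                        aims = int(rng.integers(0, 6))
                    else:
                        met = float(rng.uniform(100.0, 800.0))
                        aims = int(rng.integers(3, 6))
                    weight_ok = True
                else:
                    weight_ok = bool(rng.random() < 0.5)
                    met = float(rng.uniform(0.0, 800.0))
                    aims = int(rng.integers(0, 3))

                records.append(ParticipantRecord(
                    participant_id=f"{prefix}{pid:04d}",
                    cluster_id=f"{prefix}{j + 1}",
                    arm=arm,
                    visits_primary=alloc["visits_primary"],
                    visits_specialist=alloc["visits_specialist"],
                    visits_diabetes_nurse=alloc["visits_diabetes_nurse"],
                    visits_dietician=0,
                    uses_insulin=uses_insulin,
                    hospital_days_pre_post=alloc["hospital_days_pre_post"],
                    delivery_mode=mode,
                    delivery_stay_days=1 + alloc["extra_delivery_days"],
                    neonatal_stay_days=neonatal_days,
                    neonatal_icd_flag=neonatal_icd,
                    absence_days=alloc["absence_days"],
                    ogtt_count=2,
                    birth_weight_g=bw_out,
                    d15_baseline=d15_b,
                    d15_followup=d15_f,
                    vas_baseline_cm=vas_b_out,
                    vas_followup_cm=vas_f_out,
                    weight_gain_within_limits=weight_ok,
                    met_min_week_late=round(met, 1),
                    dietary_aims_met=aims,
                    age=float(np.clip(np.round(rng.normal(29.7, 4.8), 1), 18.0, 45.0)),
                    education_level=int(rng.choice([1, 2, 3], p=[0.34, 0.42, 0.24])),
                    bmi=float(np.clip(np.round(rng.normal(26.3, 4.7), 1), 17.0, 45.0)),
                    married=bool(rng.random() < 0.9),
                ))
    if clamped:
        warnings.warn(f"{clamped} drawn cost(s) fell below the fixed component floor "
                      "and were clamped", stacklevel=2)
    dataset = TrialDataset(records=records)
    truth = GroundTruth(
        delta_cost=params.cost_mean[0] - params.cost_mean[1],
        delta_effect={
            "birth_weight": params.bw_mean[1] - params.bw_mean[0],   # grams avoided
            "d15_change": params.d15_change_mean[0] - params.d15_change_mean[1],
            "vas_change": params.vas_change_mean[0] - params.vas_change_mean[1],
        },
        icc={"cost": params.icc_cost, "birth_weight": params.icc_bw,
             "d15": params.icc_d15, "vas": params.icc_vas},
        rho_cost_effect=params.rho_cost_effect,
        seed=params.seed if seed is None else seed,
    )
    return dataset, truth


def estimate_icc(values, clusters) -> float:
    """One-way ANOVA intracluster correlation estimate, clamped to [0, 1).

    sigma_B^2 is estimated as (MSB - MSW) / n0 with n0 the ANOVA average
    cluster size; the ICC is sigma_B^2 / (sigma_B^2 + MSW).
    """
    y = np.asarray(values, dtype=float)
    clusters = np.asarray(clusters)
    ids = list(dict.fromkeys(clusters.tolist()))
    if len(ids) < 2:
        raise TrialDataError("estimate_icc needs at least 2 clusters")
    codes = np.array([ids.index(c) for c in clusters.tolist()])
    n_j = np.bincount(codes).astype(float)
    means = np.bincount(codes, weights=y) / n_j
    grand = y.mean()
    N, M = y.size, len(ids)
    ssb = np.sum(n_j * (means - grand) ** 2)
    ssw = np.sum((y - means[codes]) ** 2)
    msb = ssb / (M - 1)
    msw = ssw / max(N - M, 1)
    n0 = (N - np.sum(n_j ** 2) / N) / (M - 1)
    sigma_b2 = max((msb - msw) / n0, 0.0)
    denom = sigma_b2 + msw
    if denom == 0:
        return 0.0
    return float(min(sigma_b2 / denom, 1.0 - 1e-12))
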