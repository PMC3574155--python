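"""Cost-effectiveness analysis: ICERs, plane quadrants, acceptability curves.

Bootstrapped (delta cost, delta effect) pairs are summarised three ways: the
incremental cost-effectiveness ratio (ICER = dC/dE on the benefit-signed
scale), the distribution of replicate pairs over the four quadrants of the
cost-effectiveness plane (NE = more effective and more costly), and the
cost-effectiveness acceptability curve CEAC(lambda) = P(lambda*dE - dC >= 0),
the probability that the intervention is cost-effective at willingness-to-pay
lambda per effect unit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import costing, outcomes, tsb
from .outcomes import BENEFIT_DIRECTION, OUTCOMES, ValuationModel15D
from .trial_io import (
    INTERVENTION,
    USUAL_CARE,
    ParticipantRecord,
    TrialDataError,
    TrialDataset,
    UnitCostTable,
)

SCENARIOS = ("base", "doubled_intervention", "subgroup")

QUADRANTS = ("NE", "SE", "SW", "NW")

#: Default willingness-to-pay grids (euros per effect unit), 200 points each.
DEFAULT_LAMBDA_GRIDS = {
    "birth_weight": (0.0, 50.0),        # euros per gram avoided
    "d15_change": (0.0, 200_000.0),     # euros per 15D index unit
    "vas_change": (0.0, 10_000.0),      # euros per VAS cm
}
LAMBDA_GRID_POINTS = 200

#: Subgroup adherence threshold: MET-minutes of weekly physical activity.
MET_MINUTES_THRESHOLD = 800.0
#: ... and minimum number of the five dietary aims fulfilled.
DIETARY_AIMS_THRESHOLD = 3


@dataclass
class CeaResult:
    """Observed and bootstrapped cost-effectiveness summary for one outcome."""

    outcome: str
    scenario: str
    n_intervention: int
    n_usual_care: int
    delta_cost: float
    delta_effect: float
    ci_cost: tuple
    ci_effect: tuple
    icer: Optional[float]               # None when delta_effect == 0
    quadrant_shares: dict               # NE/SE/SW/NW percentages of R
    ceac: pd.DataFrame                  # columns: wtp, probability
    replicates: np.ndarray              # (R, 2): delta_cost, delta_effect

    def replicates_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"replicate": np.arange(1, len(self.replicates) + 1),
                             "delta_cost": self.replicates[:, 0],
                             "delta_effect": self.replicates[:, 1]})


def icer(delta_cost: float, delta_effect: float) -> Optional[float]:
    """dC / dE on the benefit-signed scale; None (undefined) when dE is zero."""
    if delta_effect == 0:
        return None
    return float(delta_cost) / float(delta_effect)


def quadrant_shares(replicates: np.ndarray) -> dict:
    """Percentage of replicate pairs in each cost-effectiveness plane quadrant.

    NE: dE > 0 and dC > 0 (strict); ties on an axis fall south/west, so the
    four counts always partition R exactly.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.ndim != 2 or reps.shape[1] != 2 or reps.shape[0] < 1:
        raise TrialDataError("replicates must be a non-empty (R, 2) array")
    dc, de = reps[:, 0], reps[:, 1]
    counts = {
        "NE": int(np.count_nonzero((de > 0) & (dc > 0))),
        "SE": int(np.count_nonzero((de > 0) & (dc <= 0))),
        "SW": int(np.count_nonzero((de <= 0) & (dc <= 0))),
        "NW": int(np.count_nonzero((de <= 0) & (dc > 0))),
    }
    R = reps.shape[0]
    assert sum(counts.values()) == R
    return {q: 100.0 * counts[q] / R for q in QUADRANTS}


def ceac(replicates: np.ndarray, lambda_grid: Sequence[float]) -> pd.DataFrame:
    """Acceptability curve: P(lambda * dE - dC >= 0) over the grid."""
    lams = np.asarray(lambda_grid, dtype=float)
    if lams.size == 0:
        raise TrialDataError("lambda grid must not be empty")
    if np.any(lams < 0):
        raise TrialDataError("willingness-to-pay values must be >= 0")
    reps = np.asarray(replicates, dtype=float)
    nmb = lams[:, None] * reps[None, :, 1] - reps[None, :, 0]
    prob = np.count_nonzero(nmb >= 0, axis=1) / reps.shape[0]
    return pd.DataFrame({"wtp": lams, "probability": prob})


def default_lambda_grid(outcome: str) -> np.ndarray:
    lo, hi = DEFAULT_LAMBDA_GRIDS[outcome]
    return np.linspace(lo, hi, LAMBDA_GRID_POINTS)


def is_adherent(rec: ParticipantRecord) -> bool:
    """Adherence: weight gain within limits AND (>800 MET-min/week OR >=3 of 5
    dietary aims).  A missing adherence field never counts as adherent."""
    if rec.weight_gain_within_limits is not True:
        return False
    met_ok = rec.met_min_week_late is not None and rec.met_min_week_late > MET_MINUTES_THRESHOLD
    diet_ok = rec.dietary_aims_met is not None and rec.dietary_aims_met >= DIETARY_AIMS_THRESHOLD
    return met_ok or diet_ok


def subgroup_filter(records: Sequence[ParticipantRecord]) -> list:
    """Adherent subset of intervention-arm records (lifestyle targets met)."""
    return [r for r in records if is_adherent(r)]


def analyse(dataset: TrialDataset, unit_costs: UnitCostTable, outcome: str,
            config: tsb.BootstrapConfig, scenario: str = "base",
            valuation_model: Optional[ValuationModel15D] = None,
            lambda_grid: Optional[Sequence[float]] = None,
            impute: bool = True) -> CeaResult:
    """Full pipeline for one outcome and scenario.

    Runs costing -> outcome construction -> two-stage bootstrap -> BCa / ICER /
    plane / CEAC.  ``doubled_intervention`` doubles the per-person intervention
    cost; ``subgroup`` replaces the intervention arm by its adherent women
    (full usual-care arm retained).  The analysis set is the intersection of
    participants with cost data and with the outcome, so pairs stay aligned.
    """
    if scenario not in SCENARIOS:
        raise TrialDataError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if outcome not in OUTCOMES:
        raise TrialDataError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    table = unit_costs
    if scenario == "doubled_intervention":
        table = replace(unit_costs,
                        scenario_multiplier_intervention=2.0 * unit_costs.scenario_multiplier_intervention)
    work = dataset
    if scenario == "subgroup":
        adherent = subgroup_filter(dataset.arm_records(INTERVENTION))
        if not adherent:
            raise TrialDataError("empty subgroup: no intervention-arm woman meets "
                                 "the adherence criteria")
        work = TrialDataset(records=adherent + dataset.arm_records(USUAL_CARE))
    work.require_two_clusters_per_arm()

    if outcome == "d15_change" and impute:
        if valuation_model is None:
            raise TrialDataError("the 15D outcome needs a valuation model")
        work, _ = outcomes.impute_15d(work, valuation_model)

    cost_frame = costing.total_costs_frame(work, table)[
        ["participant_id", "cluster_id", "arm", "total"]]
    effect_frame = outcomes.effect_values(work, outcome, model=valuation_model)
    merged = cost_frame.merge(effect_frame[["participant_id", "value"]],
                              on="participant_id", how="inner")
    direction = BENEFIT_DIRECTION[outcome]
    merged["effect_signed"] = merged["value"] if direction == "higher_is_better" else -merged["value"]

    iv = merged[merged["arm"] == INTERVENTION]
    uv = merged[merged["arm"] == USUAL_CARE]
    if iv.empty or uv.empty:
        raise TrialDataError(f"empty analysis set for outcome {outcome!r}")
    delta_cost = float(iv["total"].mean() - uv["total"].mean())
    delta_effect = outcomes.incremental_effect(iv["value"], uv["value"], direction)

    replicates = tsb.tsb_resample(merged["total"].to_numpy(),
                                  merged["effect_signed"].to_numpy(),
                                  merged["cluster_id"].to_numpy(),
                                  merged["arm"].to_numpy(), config)
    jack_cost = tsb.jackknife_cluster_deltas(merged["total"].to_numpy(),
                                             merged["cluster_id"].to_numpy(),
                                             merged["arm"].to_numpy())
    jack_eff = tsb.jackknife_cluster_deltas(merged["effect_signed"].to_numpy(),
                                            merged["cluster_id"].to_numpy(),
                                            merged["arm"].to_numpy())
    ci_cost = tsb.bca_interval(replicates[:, 0], delta_cost, jack_cost, level=config.level)
    ci_effect = tsb.bca_interval(replicates[:, 1], delta_effect, jack_eff, level=config.level)

    grid = np.asarray(lambda_grid, dtype=float) if lambda_grid is not None \
        else default_lambda_grid(outcome)
    return CeaResult(outcome=outcome, scenario=scenario,
                     n_intervention=len(iv), n_usual_care=len(uv),
                     delta_cost=delta_cost, delta_effect=delta_effect,
                     ci_cost=ci_cost, ci_effect=ci_effect,
                     icer=icer(delta_cost, delta_effect),
                     quadrant_shares=quadrant_shares(replicates),
                     ceac=ceac(replicates, grid),
                     replicates=replicates)
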