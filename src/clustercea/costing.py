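"""Per-woman component costs and totals from service use and the unit-cost table.

Costing follows the societal perspective of the trial's economic evaluation:
municipal health-care costs, costs borne by the patient, productivity losses,
and the intervention's own delivery cost, from the beginning of pregnancy to
the last hospital day of mother and newborn.  All arithmetic is carried
unrounded; euro rounding (half-up) happens only when a report is rendered.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .trial_io import (
    INTERVENTION,
    ParticipantRecord,
    TrialDataset,
    TrialDataError,
    UnitCostTable,
)

#: Patient charge for a neonatal stay applies for at most this many days.
NEONATAL_CHARGE_CAP_DAYS = 7

COMPONENTS = (
    "primary_care", "specialist", "diabetes_nurse", "dietician", "ogtt",
    "insulin", "hospital_pre_post", "delivery_patient", "delivery_municipality",
    "neonatal_patient", "neonatal_municipality", "productivity", "intervention",
)

#: Components counted as direct health-care costs: everything except
#: productivity losses and the intervention's own delivery cost.
DIRECT_COMPONENTS = tuple(c for c in COMPONENTS if c not in ("productivity", "intervention"))


@dataclass
class CostBreakdown:
    """Component costs (euros, 2009) and totals for one woman."""

    primary_care: float = 0.0
    specialist: float = 0.0
    diabetes_nurse: float = 0.0
    dietician: float = 0.0
    ogtt: float = 0.0
    insulin: float = 0.0
    hospital_pre_post: float = 0.0
    delivery_patient: float = 0.0
    delivery_municipality: float = 0.0
    neonatal_patient: float = 0.0
    neonatal_municipality: float = 0.0
    productivity: float = 0.0
    intervention: float = 0.0

    @property
    def direct_total(self) -> float:
        return sum(getattr(self, c) for c in DIRECT_COMPONENTS)

    @property
    def total(self) -> float:
        return sum(getattr(self, c) for c in COMPONENTS)

    def as_dict(self) -> dict:
        d = {c: getattr(self, c) for c in COMPONENTS}
        d["direct_total"] = self.direct_total
        d["total"] = self.total
        return d


def round_euro(x: float) -> int:
    """Round to the nearest euro, half away from zero (report precision)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def component_cost(units: float, unit_price: float) -> float:
    """units x price, unrounded (e.g. 14.5 visits x 72 = 1044.0)."""
    if units < 0:
        raise TrialDataError(f"units must be >= 0, got {units}")
    if unit_price < 0:
        raise TrialDataError(f"unit price must be >= 0, got {unit_price}")
    return units * unit_price


def intervention_cost(table: UnitCostTable) -> float:
    """Per-person cost of delivering the counselling intervention.

    Supplemental public-health-nurse time plus the physiotherapist's group
    sessions, scaled by the scenario multiplier (1.0 base, 2.0 for the
    doubled-cost sensitivity scenario).  Applied to intervention-arm women only
    (the arm gating lives in :func:`total_cost`).
    """
    base = (table.intervention_nurse_hours * table.nurse_hour + table.physio_contribution)
    return base * table.scenario_multiplier_intervention


def productivity_cost(absence_days: float, table: UnitCostTable) -> float:
    """Self-reported workdays lost x daily salary cost (default 189 euros/day)."""
    if absence_days < 0:
        raise TrialDataError(f"absence_days must be >= 0, got {absence_days}")
    return absence_days * table.absence_day * table.salary_overhead_multiplier


def patient_inpatient_charge(days: float, table: UnitCostTable,
                             cap: Optional[int] = None) -> float:
    """Standard patient daily charge (30 euros/day), optionally capped.

    The neonatal charge is levied over at most :data:`NEONATAL_CHARGE_CAP_DAYS`
    hospital days; the mother's delivery-stay charge is uncapped.
    """
    if days < 0:
        raise TrialDataError(f"days must be >= 0, got {days}")
    billable = min(days, cap) if cap is not None else days
    return billable * table.inpatient_daily_charge


def total_cost(record: ParticipantRecord, table: UnitCostTable) -> CostBreakdown:
    """Every cost component for one woman, assembled from her service use."""
    bd = CostBreakdown(
        primary_care=component_cost(record.visits_primary, table.primary_visit),
        specialist=component_cost(record.visits_specialist, table.specialist_visit),
        diabetes_nurse=component_cost(record.visits_diabetes_nurse, table.diabetes_nurse_hour),
        dietician=component_cost(record.visits_dietician, table.dietician_hour),
        ogtt=component_cost(record.ogtt_count, table.ogtt_test),
        insulin=table.insulin_course if record.uses_insulin else 0.0,
        hospital_pre_post=component_cost(record.hospital_days_pre_post, table.hospital_day),
        delivery_patient=patient_inpatient_charge(record.delivery_stay_days, table),
        neonatal_patient=patient_inpatient_charge(record.neonatal_stay_days, table,
                                                  cap=NEONATAL_CHARGE_CAP_DAYS),
        productivity=productivity_cost(record.absence_days, table),
    )
    if record.delivery_mode is not None:
        prices = table.delivery_mode_prices or {}
        if record.delivery_mode not in prices:
            raise TrialDataError(
                f"no delivery price configured for mode {record.delivery_mode!r} "
                f"(participant {record.participant_id!r})")
        bd.delivery_municipality = prices[record.delivery_mode]
    if record.neonatal_icd_flag:
        if table.neonatal_day is None:
            raise TrialDataError(
                "neonatal_day price not configured but record "
                f"{record.participant_id!r} has an ICD-flagged neonatal stay")
        bd.neonatal_municipality = component_cost(record.neonatal_stay_days, table.neonatal_day)
    if record.arm == INTERVENTION:
        bd.intervention = intervention_cost(table)
    return bd


def total_costs_frame(dataset: TrialDataset, table: UnitCostTable) -> pd.DataFrame:
    """Per-participant cost breakdowns as a tidy DataFrame (unrounded euros)."""
    rows = []
    for rec in dataset.records:
        row = {"participant_id": rec.participant_id, "cluster_id": rec.cluster_id,
               "arm": rec.arm}
        row.update(total_cost(rec, table).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def arm_summary(dataset: TrialDataset, table: UnitCostTable) -> pd.DataFrame:
    """Arithmetic mean and SD of each cost component and total, by arm.

    Returns a tidy frame with columns ``arm, component, mean, sd`` in unrounded
    euros; report rendering applies euro rounding.  An empty arm is an error.
    """
    frame = total_costs_frame(dataset, table)
    out = []
    for arm in sorted(frame["arm"].unique()):
        sub = frame[frame["arm"] == arm]
        if sub.empty:
            raise TrialDataError(f"arm {arm!r} has no records")
        for comp in COMPONENTS + ("direct_total", "total"):
            vals = sub[comp].to_numpy(dtype=float)
            out.append({"arm": arm, "component": comp,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0})
    for arm in dataset.clusters_per_arm:
        if not any(r["arm"] == arm for r in out):
            raise TrialDataError(f"arm {arm!r} has no records")
    return pd.DataFrame(out)
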