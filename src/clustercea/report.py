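"""Report rendering: cost table, CEA table, plane/CEAC data files, run log.

Rounding happens here and only here: euros half-up to whole units, plane
shares to one decimal, per-gram ICERs to two decimals, other ICERs to whole
euros.  Every rendered number equals the in-memory value after that single
rounding step.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cea import CeaResult
from .costing import COMPONENTS, arm_summary, round_euro
from .trial_io import INTERVENTION, USUAL_CARE, TrialDataset, UnitCostTable

#: Mean service units per woman shown next to each component, where defined.
_UNIT_FIELDS = {
    "primary_care": "visits_primary",
    "specialist": "visits_specialist",
    "diabetes_nurse": "visits_diabetes_nurse",
    "dietician": "visits_dietician",
    "ogtt": "ogtt_count",
    "hospital_pre_post": "hospital_days_pre_post",
    "delivery_patient": "delivery_stay_days",
    "neonatal_patient": "neonatal_stay_days",
    "productivity": "absence_days",
}


def _round_icer(value: Optional[float], outcome: str):
    if value is None:
        return "undefined"
    if outcome == "birth_weight":
        return round(value, 2)
    return round_euro(value)


def cost_table(dataset: TrialDataset, table: UnitCostTable) -> pd.DataFrame:
    """Component-by-arm cost table (mean units, mean +- SD euros, rounded)."""
    summary = arm_summary(dataset, table)
    rows = []
    for comp in COMPONENTS + ("direct_total", "total"):
        row = {"component": comp}
        for arm in (INTERVENTION, USUAL_CARE):
            recs = dataset.arm_records(arm)
            sub = summary[(summary["arm"] == arm) & (summary["component"] == comp)]
            if sub.empty:
                continue
            units = ""
            if comp in _UNIT_FIELDS:
                vals = [getattr(r, _UNIT_FIELDS[comp]) for r in recs]
                units = round(float(np.mean(vals)), 2)
            row[f"units_{arm}"] = units
            row[f"mean_{arm}"] = round_euro(float(sub["mean"].iloc[0]))
            row[f"sd_{arm}"] = round_euro(float(sub["sd"].iloc[0]))
        rows.append(row)
    return pd.DataFrame(rows)


def cea_table(results: Iterable[CeaResult]) -> pd.DataFrame:
    """One row per outcome x scenario, mirroring the published result layout."""
    rows = []
    for res in results:
        rows.append({
            "scenario": res.scenario,
            "outcome": res.outcome,
            "n_intervention": res.n_intervention,
            "n_usual_care": res.n_usual_care,
            "delta_cost": round_euro(res.delta_cost),
            "cost_ci_low": round_euro(res.ci_cost[0]),
            "cost_ci_high": round_euro(res.ci_cost[1]),
            "delta_effect": round(res.delta_effect, 4),
            "effect_ci_low": round(res.ci_effect[0], 4),
            "effect_ci_high": round(res.ci_effect[1], 4),
            "icer": _round_icer(res.icer, res.outcome),
            "NE": round(res.quadrant_shares["NE"], 1),
            "SE": round(res.quadrant_shares["SE"], 1),
            "SW": round(res.quadrant_shares["SW"], 1),
            "NW": round(res.quadrant_shares["NW"], 1),
        })
    return pd.DataFrame(rows)


def write_result_bundle(results: Iterable[CeaResult], out_dir,
                        dataset: Optional[TrialDataset] = None,
                        table: Optional[UnitCostTable] = None,
                        run_info: Optional[dict] = None,
                        figures: bool = False) -> list:
    """Write the CEA table plus per-result plane/CEAC CSVs (and figures).

    Returns the list of paths written.  ``run_info`` (seed, R, config) is
    dumped as a YAML run log alongside the tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    results = list(results)
    path = out / "cea_table.csv"
    cea_table(results).to_csv(path, index=False)
    written.append(path)
    if dataset is not None and table is not None:
        path = out / "cost_table.csv"
        cost_table(dataset, table).to_csv(path, index=False)
        written.append(path)
    for res in results:
        stem = f"{res.outcome}_{res.scenario}"
        p = out / f"plane_{stem}.csv"
        res.replicates_frame().to_csv(p, index=False)
        written.append(p)
        p = out / f"ceac_{stem}.csv"
        res.ceac.to_csv(p, index=False)
        written.append(p)
        if figures:
            written.extend(_write_figures(res, out, stem))
    log = {"package_version": __version__,
           "numpy_version": np.__version__,
           "pandas_version": pd.__version__}
    if run_info:
        log.update(run_info)
    path = out / "run_log.yml"
    with open(path, "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    written.append(path)
    return written


def _write_figures(res: CeaResult, out: Path, stem: str) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 8))
    ax1.scatter(res.replicates[:, 1], res.replicates[:, 0], s=4, alpha=0.4)
    ax1.axhline(0, color="grey", lw=0.8)
    ax1.axvline(0, color="grey", lw=0.8)
    ax1.set_xlabel(f"incremental effect ({res.outcome})")
    ax1.set_ylabel("incremental cost (EUR)")
    ax1.set_title("cost-effectiveness plane")
    ax2.plot(res.ceac["wtp"], res.ceac["probability"])
    ax2.set_ylim(0, 1)
    ax2.set_xlabel("willingness to pay (EUR per effect unit)")
    ax2.set_ylabel("P(cost-effective)")
    ax2.set_title("acceptability curve")
    fig.tight_layout()
    path = out / f"figure_{stem}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return [path]
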