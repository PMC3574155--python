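"""Data model, readers/writers and validation for trial datasets and unit-cost config.

Trial data are long-format, one row per woman, with the cluster (maternity
clinic) and trial arm stored on each row.  Files are UTF-8 CSV with a header;
missing values are an empty field or ``NA`` on read, written back as ``NA``.
Unit costs and scenario settings live in a YAML config (2009 euros throughout).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd
import yaml

INTERVENTION = "intervention"
USUAL_CARE = "usual_care"
ARMS = (INTERVENTION, USUAL_CARE)

DELIVERY_MODES = ("vaginal", "instrumental", "elective_caesarean", "emergency_caesarean")

N_DIMENSIONS = 15

#: CSV column names for the 15D profiles at the two questionnaire timepoints
#: (weeks 8-13 and 36-37 of pregnancy).
D15_BASELINE_COLS = tuple(f"d15_b{i:02d}" for i in range(1, N_DIMENSIONS + 1))
D15_FOLLOWUP_COLS = tuple(f"d15_f{i:02d}" for i in range(1, N_DIMENSIONS + 1))

MISSING_TOKENS = ("", "NA")


class TrialDataError(ValueError):
    """Raised when a trial table or config violates the data contract."""


@dataclass
class ParticipantRecord:
    """One woman in the trial: service use, outcomes and adherence fields.

    Counts are non-negative integers; 15D levels are 1 (best) to 5 (worst),
    stored as floats so that regression-imputed fractional levels can be kept;
    VAS is self-rated health on a 0-10 cm scale.
    """

    participant_id: str
    cluster_id: str
    arm: str
    visits_primary: int = 0
    visits_specialist: int = 0
    visits_diabetes_nurse: int = 0
    visits_dietician: int = 0
    uses_insulin: bool = False
    hospital_days_pre_post: int = 0
    delivery_mode: Optional[str] = None
    delivery_stay_days: int = 0
    neonatal_stay_days: int = 0
    neonatal_icd_flag: bool = False
    absence_days: int = 0
    ogtt_count: int = 2
    birth_weight_g: Optional[float] = None
    d15_baseline: Optional[list] = None
    d15_followup: Optional[list] = None
    vas_baseline_cm: Optional[float] = None
    vas_followup_cm: Optional[float] = None
    weight_gain_within_limits: Optional[bool] = None
    met_min_week_late: Optional[float] = None
    dietary_aims_met: Optional[int] = None
    age: Optional[float] = None
    education_level: Optional[int] = None
    bmi: Optional[float] = None
    married: Optional[bool] = None

    def validate(self, where: str = "") -> None:
        ctx = f"{where}: " if where else ""
        if self.arm not in ARMS:
            raise TrialDataError(f"{ctx}unknown arm label {self.arm!r}")
        if self.delivery_mode is not None and self.delivery_mode not in DELIVERY_MODES:
            raise TrialDataError(f"{ctx}unknown delivery mode {self.delivery_mode!r}")
        for name in ("visits_primary", "visits_specialist", "visits_diabetes_nurse",
                     "visits_dietician", "hospital_days_pre_post", "delivery_stay_days",
                     "neonatal_stay_days", "absence_days", "ogtt_count"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise TrialDataError(f"{ctx}field {name!r} must be a non-negative integer, got {v!r}")
        for name in ("vas_baseline_cm", "vas_followup_cm"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 10.0):
                raise TrialDataError(f"{ctx}field {name!r} out of range [0, 10]: {v!r}")
        if self.birth_weight_g is not None and not self.birth_weight_g > 0:
            raise TrialDataError(f"{ctx}field 'birth_weight_g' must be > 0, got {self.birth_weight_g!r}")
        for name in ("d15_baseline", "d15_followup"):
            profile = getattr(self, name)
            if profile is None:
                continue
            if len(profile) != N_DIMENSIONS:
                raise TrialDataError(f"{ctx}field {name!r} must have {N_DIMENSIONS} entries")
            for d, lev in enumerate(profile, start=1):
                if lev is not None and not (1.0 <= float(lev) <= 5.0):
                    raise TrialDataError(
                        f"{ctx}field {name!r} dimension {d} level out of range [1, 5]: {lev!r}")
        if self.dietary_aims_met is not None and not (0 <= self.dietary_aims_met <= 5):
            raise TrialDataError(f"{ctx}field 'dietary_aims_met' out of range 0-5: {self.dietary_aims_met!r}")


@dataclass
class TrialDataset:
    """A validated collection of participant records with the cluster structure."""

    records: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen = set()
        cluster_arm: dict = {}
        for rec in self.records:
            rec.validate(where=f"participant {rec.participant_id!r}")
            if rec.participant_id in seen:
                raise TrialDataError(f"duplicate participant_id {rec.participant_id!r}")
            seen.add(rec.participant_id)
            prev = cluster_arm.get(rec.cluster_id)
            if prev is not None and prev != rec.arm:
                raise TrialDataError(
                    f"cluster in two arms: cluster {rec.cluster_id!r} appears in "
                    f"both {prev!r} and {rec.arm!r}")
            cluster_arm[rec.cluster_id] = rec.arm

    @property
    def clusters_per_arm(self) -> dict:
        out: dict = {a: [] for a in ARMS}
        for rec in self.records:
            if rec.cluster_id not in out[rec.arm]:
                out[rec.arm].append(rec.cluster_id)
        return out

    def arm_records(self, arm: str) -> list:
        return [r for r in self.records if r.arm == arm]

    def require_two_clusters_per_arm(self) -> None:
        for arm, clusters in self.clusters_per_arm.items():
            if len(clusters) < 2:
                raise TrialDataError(
                    f"arm {arm!r} has {len(clusters)} cluster(s); the two-stage "
                    "bootstrap needs at least 2 clusters per arm")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# CSV serialisation

_COUNT_FIELDS = ("visits_primary", "visits_specialist", "visits_diabetes_nurse",
                 "visits_dietician", "hospital_days_pre_post", "delivery_stay_days",
                 "neonatal_stay_days", "absence_days", "ogtt_count")
_BOOL_FIELDS = ("uses_insulin", "neonatal_icd_flag", "weight_gain_within_limits", "married")
_FLOAT_FIELDS = ("birth_weight_g", "vas_baseline_cm", "vas_followup_cm",
                 "met_min_week_late", "age", "bmi")
_INT_OPTIONAL_FIELDS = ("dietary_aims_met", "education_level")


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and value != value):
        return "NA"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def dataset_to_frame(dataset: TrialDataset) -> pd.DataFrame:
    """Flatten a TrialDataset to a long-format DataFrame (one row per woman)."""
    rows = []
    for rec in dataset.records:
        row = {"participant_id": rec.participant_id, "cluster_id": rec.cluster_id,
               "arm": rec.arm}
        for name in _COUNT_FIELDS + _BOOL_FIELDS + _FLOAT_FIELDS + _INT_OPTIONAL_FIELDS:
            row[name] = getattr(rec, name)
        row["delivery_mode"] = rec.delivery_mode
        for cols, profile in ((D15_BASELINE_COLS, rec.d15_baseline),
                              (D15_FOLLOWUP_COLS, rec.d15_followup)):
            for i, col in enumerate(cols):
                row[col] = None if profile is None else profile[i]
        rows.append(row)
    return pd.DataFrame(rows)


def write_trial_table(dataset: TrialDataset, path) -> None:
    """Write a TrialDataset to CSV, with ``NA`` for every missing value."""
    frame = dataset_to_frame(dataset)
    text_frame = frame.map(_fmt)
    text_frame.to_csv(path, index=False)


def _parse(value: str, kind: str, row: int, name: str):
    if value is None or str(value).strip() in MISSING_TOKENS:
        return None
    s = str(value).strip()
    try:
        if kind == "int":
            f = float(s)
            if f != int(f):
                raise ValueError
            return int(f)
        if kind == "float":
            return float(s)
        if kind == "bool":
            if s in ("1", "True", "true"):
                return True
            if s in ("0", "False", "false"):
                return False
            raise ValueError
    except ValueError:
        raise TrialDataError(f"row {row}: field {name!r}: cannot parse {s!r} as {kind}") from None
    return s


def read_trial_table(path, schema: Optional[Mapping[str, str]] = None) -> TrialDataset:
    """Read and validate a long-format trial CSV.

    Parameters
    ----------
    path : file path
        CSV with a header row.
    schema : mapping, optional
        Renames file columns to canonical field names (``{file_col: field}``)
        before parsing, for tables exported under different headers.

    Raises :class:`TrialDataError` with a row-addressed message on any
    malformed or invariant-violating input; there are no partial loads.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        frame = frame.rename(columns=dict(schema))
    required = ("participant_id", "cluster_id", "arm")
    for col in required:
        if col not in frame.columns:
            raise TrialDataError(f"missing required column {col!r}")
    records = []
    for i, raw in enumerate(frame.to_dict("records"), start=2):  # header is row 1
        kwargs = {}
        for key in required:
            v = str(raw[key]).strip()
            if v in MISSING_TOKENS:
                raise TrialDataError(f"row {i}: field {key!r} is missing")
            kwargs[key] = v
        for name in _COUNT_FIELDS:
            v = _parse(raw.get(name), "int", i, name)
            if v is not None:
                if v < 0:
                    raise TrialDataError(f"row {i}: field {name!r} must be non-negative, got {v}")
                kwargs[name] = v
        for name in _BOOL_FIELDS:
            v = _parse(raw.get(name), "bool", i, name)
            if v is not None or name in ("weight_gain_within_limits", "married"):
                kwargs[name] = v if v is not None else None
        for name in _FLOAT_FIELDS:
            kwargs[name] = _parse(raw.get(name), "float", i, name)
        for name in _INT_OPTIONAL_FIELDS:
            kwargs[name] = _parse(raw.get(name), "int", i, name)
        mode = raw.get("delivery_mode")
        mode = None if mode is None or str(mode).strip() in MISSING_TOKENS else str(mode).strip()
        kwargs["delivery_mode"] = mode
        for cols, name in ((D15_BASELINE_COLS, "d15_baseline"),
                           (D15_FOLLOWUP_COLS, "d15_followup")):
            if all(c in frame.columns for c in cols):
                profile = [_parse(raw.get(c), "float", i, c) for c in cols]
                kwargs[name] = None if all(p is None for p in profile) else profile
        rec = ParticipantRecord(**{k: v for k, v in kwargs.items() if k in
                                   {f.name for f in dataclasses.fields(ParticipantRecord)}})
        try:
            rec.validate(where=f"row {i}")
        except TrialDataError:
            raise
        records.append(rec)
    return TrialDataset(records=records)


# ---------------------------------------------------------------------------
# Unit-cost configuration

#: Price keys that must be present in every unit-cost config (euros, 2009).
REQUIRED_PRICE_KEYS = (
    "primary_visit", "specialist_visit", "diabetes_nurse_hour", "dietician_hour",
    "ogtt_test", "insulin_course", "hospital_day", "inpatient_daily_charge",
    "absence_day", "nurse_hour", "physio_contribution",
)


@dataclass
class UnitCostTable:
    """Prices per service unit, 2009 euros, plus scenario settings.

    Delivery municipality prices by mode and the neonatal per-day price are not
    published unit costs; they must be provided explicitly in the config — a
    record needing one of them fails costing loudly rather than costing zero.
    """

    primary_visit: float = 72.0
    specialist_visit: float = 208.0
    diabetes_nurse_hour: float = 91.0
    dietician_hour: float = 164.0
    ogtt_test: float = 25.0
    insulin_course: float = 85.0            # one 2.5-month course
    hospital_day: float = 330.0
    inpatient_daily_charge: float = 30.0    # patient's standard daily charge
    absence_day: float = 189.0              # salary cost per workday lost
    nurse_hour: float = 56.0
    physio_contribution: float = 23.0       # physiotherapist group sessions, per person
    intervention_nurse_hours: float = 2.1   # supplemental counselling time per woman
    scenario_multiplier_intervention: float = 1.0
    salary_overhead_multiplier: float = 1.0
    delivery_mode_prices: Optional[dict] = None   # municipality cost by delivery mode
    neonatal_day: Optional[float] = None          # municipality cost per neonatal day (ICD cases)

    def __post_init__(self):
        for key in REQUIRED_PRICE_KEYS + ("intervention_nurse_hours",):
            v = getattr(self, key)
            if v is None or v < 0:
                raise TrialDataError(f"unit cost {key!r} must be >= 0, got {v!r}")
        if not self.scenario_multiplier_intervention > 0:
            raise TrialDataError("scenario_multiplier_intervention must be > 0")
        if self.delivery_mode_prices:
            for mode, price in self.delivery_mode_prices.items():
                if mode not in DELIVERY_MODES:
                    raise TrialDataError(f"unknown delivery mode in prices: {mode!r}")
                if price < 0:
                    raise TrialDataError(f"negative delivery price for {mode!r}")
        if self.neonatal_day is not None and self.neonatal_day < 0:
            raise TrialDataError("neonatal_day price must be >= 0")


def read_unit_costs(path) -> UnitCostTable:
    """Read a YAML unit-cost config into a :class:`UnitCostTable`.

    All keys in :data:`REQUIRED_PRICE_KEYS` must be present; negative prices
    are rejected.  Delivery-mode and neonatal prices are optional here but
    required at costing time for records that use them.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    missing = [k for k in REQUIRED_PRICE_KEYS if k not in raw]
    if missing:
        raise TrialDataError(f"unit-cost config missing required key(s): {', '.join(missing)}")
    known = {f.name for f in dataclasses.fields(UnitCostTable)}
    unknown = [k for k in raw if k not in known]
    if unknown:
        raise TrialDataError(f"unknown unit-cost key(s): {', '.join(unknown)}")
    return UnitCostTable(**raw)


def write_unit_costs(table: UnitCostTable, path) -> None:
    data = dataclasses.asdict(table)
    data = {k: v for k, v in data.items() if v is not None}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
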