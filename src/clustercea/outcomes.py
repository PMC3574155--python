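"""Effect measures: birth weight, 15D utility change, and VAS change.

The 15D instrument covers fifteen health dimensions (mobility, vision, ...,
sexual activity), each answered on five levels (1 best .. 5 worst).  A
valuation model maps each level to a value in [0, 1] and combines the fifteen
dimension values with importance weights into a single utility index, 1 for
full health.  The published Finnish valuation weights are licensed and not
shipped; the model is a config input.  :meth:`ValuationModel15D.equal_weights`
provides a synthetic equal-weight, linear-value model for testing and
simulation only — it is not the licensed tariff.

Partially missing 15D answers (at most six dimensions at a timepoint) are
imputed by linear regression of the missing dimension's level value on the
other dimensions' level values plus age, education, BMI and marital status,
fitted over complete cases with both arms pooled.  Profiles with more than six
missing dimensions at a timepoint are excluded from 15D analyses, never
imputed.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .trial_io import (
    INTERVENTION,
    N_DIMENSIONS,
    TrialDataError,
    TrialDataset,
    USUAL_CARE,
)

OUTCOMES = ("birth_weight", "d15_change", "vas_change")

#: Whether a larger raw value of the measure is a health gain.  Birth weight is
#: analysed as grams *avoided* in a macrosomia-risk population, so lower raw
#: values are the benefit.
BENEFIT_DIRECTION = {
    "birth_weight": "lower_is_better",
    "d15_change": "higher_is_better",
    "vas_change": "higher_is_better",
}

#: Maximum number of missing dimensions at a timepoint that may be imputed.
MAX_IMPUTABLE_DIMENSIONS = 6

IMPUTATION_COVARIATES = ("age", "education_level", "bmi", "married")

TIMEPOINTS = ("baseline", "followup")

LEVELS = np.arange(1, 6, dtype=float)


@dataclass
class ValuationModel15D:
    """Additive 15D valuation: index = sum_d w_d * v_d(level_d).

    ``level_values`` is a (15, 5) grid with v_d(1) = 1 and values strictly
    decreasing in the level; ``weights`` are non-negative and sum to 1, so the
    best profile scores exactly 1.
    """

    weights: np.ndarray
    level_values: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.level_values = np.asarray(self.level_values, dtype=float)
        if self.weights.shape != (N_DIMENSIONS,):
            raise TrialDataError("valuation weights must have 15 entries")
        if self.level_values.shape != (N_DIMENSIONS, 5):
            raise TrialDataError("level values must be a 15 x 5 grid")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise TrialDataError("valuation weights must be >= 0 and sum to 1")
        if not np.allclose(self.level_values[:, 0], 1.0):
            raise TrialDataError("best level (1) must have value 1 in every dimension")
        if np.any(np.diff(self.level_values, axis=1) >= 0):
            raise TrialDataError("level values must decrease strictly with worsening level")
        if np.any(self.level_values < 0) or np.any(self.level_values > 1):
            raise TrialDataError("level values must lie in [0, 1]")

    @classmethod
    def equal_weights(cls) -> "ValuationModel15D":
        """Synthetic model: equal weights 1/15, linear values 1, .75, .5, .25, 0."""
        values = np.tile(1.0 - (LEVELS - 1.0) / 4.0, (N_DIMENSIONS, 1))
        return cls(weights=np.full(N_DIMENSIONS, 1.0 / N_DIMENSIONS), level_values=values)

    def dimension_value(self, dim: int, level: float) -> float:
        """Value of one dimension at a (possibly fractional) level."""
        if not (1.0 <= level <= 5.0):
            raise TrialDataError(f"level {level!r} out of range [1, 5]")
        return float(np.interp(level, LEVELS, self.level_values[dim]))

    def level_from_value(self, dim: int, value: float) -> float:
        """Inverse of :meth:`dimension_value`, clipping to the value range."""
        vals = self.level_values[dim]
        value = float(np.clip(value, vals.min(), vals.max()))
        # values decrease with level: interpolate on the reversed grid
        return float(np.interp(value, vals[::-1], LEVELS[::-1]))

    def score(self, levels: Sequence[float]) -> float:
        levels = list(levels)
        if len(levels) != N_DIMENSIONS:
            raise TrialDataError("a 15D profile needs 15 levels")
        missing = [d + 1 for d, lev in enumerate(levels) if lev is None]
        if missing:
            raise TrialDataError(
                f"cannot score a profile with missing dimension(s) {missing}; "
                "impute first (impute_15d)")
        vals = np.array([self.dimension_value(d, float(lev)) for d, lev in enumerate(levels)])
        # computed as 1 - weighted deficit so the best profile scores exactly 1
        return 1.0 - float(np.dot(self.weights, 1.0 - vals))

    @classmethod
    def from_yaml(cls, path) -> "ValuationModel15D":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(weights=np.asarray(raw["weights"], dtype=float),
                   level_values=np.asarray(raw["level_values"], dtype=float))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"weights": self.weights.tolist(),
                            "level_values": self.level_values.tolist()}, fh)


def score_15d(levels: Sequence[float], model: ValuationModel15D) -> float:
    """Single utility index in [0, 1] for a complete 15D profile."""
    return model.score(levels)


def _profile_attr(timepoint: str) -> str:
    return {"baseline": "d15_baseline", "followup": "d15_followup"}[timepoint]


def _missing_count(profile) -> int:
    if profile is None:
        return N_DIMENSIONS
    return sum(1 for lev in profile if lev is None)


def _covariate_row(rec) -> Optional[np.ndarray]:
    vals = []
    for name in IMPUTATION_COVARIATES:
        v = getattr(rec, name)
        if v is None:
            return None
        vals.append(float(v))
    return np.array(vals)


def impute_15d(dataset: TrialDataset, model: ValuationModel15D):
    """Regression-impute partially missing 15D dimensions.

    For each participant-timepoint with 1..6 missing dimensions, each missing
    dimension's *level value* is regressed (OLS, unstandardised prediction) on
    the level values of the dimensions that participant did answer, plus age,
    education (ordinal 1-3), BMI and marital status (binary), over complete
    cases at the same timepoint, arms pooled.  Predictions are clipped to the
    dimension's value range and converted back to a fractional level.

    Returns ``(imputed_dataset, log)`` where ``log`` is a DataFrame with one
    row per imputed value (participant, timepoint, dimension, predicted value
    and level).  Profiles with more than six missing dimensions are left
    untouched (excluded from 15D analyses downstream).  Running the function
    on its own output is the identity.
    """
    new = TrialDataset(records=[copy.deepcopy(r) for r in dataset.records])
    log_rows = []
    for timepoint in TIMEPOINTS:
        attr = _profile_attr(timepoint)
        complete_values, complete_covs = [], []
        for rec in new.records:
            profile = getattr(rec, attr)
            if profile is not None and _missing_count(profile) == 0:
                cov = _covariate_row(rec)
                if cov is not None:
                    complete_values.append(
                        [model.dimension_value(d, float(profile[d])) for d in range(N_DIMENSIONS)])
                    complete_covs.append(cov)
        complete_values = np.asarray(complete_values)
        complete_covs = np.asarray(complete_covs)

        for rec in new.records:
            profile = getattr(rec, attr)
            k = _missing_count(profile)
            if profile is None or k == 0 or k > MAX_IMPUTABLE_DIMENSIONS:
                continue
            present = [d for d in range(N_DIMENSIONS) if profile[d] is not None]
            missing = [d for d in range(N_DIMENSIONS) if profile[d] is None]
            cov = _covariate_row(rec)
            n_predictors = len(present) + (len(IMPUTATION_COVARIATES) if cov is not None else 0) + 1
            if len(complete_values) <= n_predictors:
                raise TrialDataError(
                    f"only {len(complete_values)} complete cases at {timepoint} for "
                    f"{n_predictors} predictors; reduce the covariate set")
            for d in missing:
                X_cols = [complete_values[:, p] for p in present]
                x_new = [model.dimension_value(p, float(profile[p])) for p in present]
                if cov is not None:
                    X_cols.extend(complete_covs.T)
                    x_new.extend(cov)
                X = sm.add_constant(np.column_stack(X_cols))
                fit = sm.OLS(complete_values[:, d], X).fit()
                pred = float(fit.predict(np.concatenate(([1.0], x_new)))[0])
                vals = model.level_values[d]
                pred = float(np.clip(pred, vals.min(), vals.max()))
                level = model.level_from_value(d, pred)
                profile[d] = level
                log_rows.append({"participant_id": rec.participant_id,
                                 "timepoint": timepoint, "dimension": d + 1,
                                 "predicted_value": pred, "predicted_level": level})
    log = pd.DataFrame(log_rows, columns=["participant_id", "timepoint", "dimension",
                                          "predicted_value", "predicted_level"])
    return new, log


def d15_analysis_status(rec) -> str:
    """'complete' if both timepoints are scoreable, else why not."""
    for timepoint in TIMEPOINTS:
        k = _missing_count(getattr(rec, _profile_attr(timepoint)))
        if k > MAX_IMPUTABLE_DIMENSIONS:
            return f"excluded: {k} missing dimensions at {timepoint}"
        if k > 0:
            return f"unimputed: {k} missing dimensions at {timepoint}"
    return "complete"


def effect_values(dataset: TrialDataset, measure: str,
                  model: Optional[ValuationModel15D] = None) -> pd.DataFrame:
    """Per-participant effect values for one measure, complete cases only.

    Returns a DataFrame with columns ``participant_id, cluster_id, arm, value``.
    For the change measures, value = follow-up minus baseline; participants
    missing either timepoint (or, for 15D, with unimputable profiles) are
    dropped, so per-outcome analysis sets differ in size.
    """
    if measure not in OUTCOMES:
        raise TrialDataError(f"unknown outcome {measure!r}; expected one of {OUTCOMES}")
    rows = []
    for rec in dataset.records:
        if measure == "birth_weight":
            if rec.birth_weight_g is None:
                continue
            value = float(rec.birth_weight_g)
        elif measure == "vas_change":
            if rec.vas_baseline_cm is None or rec.vas_followup_cm is None:
                continue
            value = float(rec.vas_followup_cm) - float(rec.vas_baseline_cm)
        else:  # d15_change
            if model is None:
                raise TrialDataError("d15_change needs a ValuationModel15D")
            if d15_analysis_status(rec) != "complete":
                continue
            value = (score_15d(rec.d15_followup, model)
                     - score_15d(rec.d15_baseline, model))
        rows.append({"participant_id": rec.participant_id, "cluster_id": rec.cluster_id,
                     "arm": rec.arm, "value": value})
    frame = pd.DataFrame(rows, columns=["participant_id", "cluster_id", "arm", "value"])
    if frame.empty:
        raise TrialDataError(f"no participants with complete data for {measure!r}")
    return frame


def incremental_effect(intervention_values: Sequence[float],
                       usual_care_values: Sequence[float],
                       benefit_direction: str) -> float:
    """Benefit-signed mean effect difference, intervention vs usual care.

    For ``higher_is_better``: mean(intervention) - mean(usual care).  For
    ``lower_is_better`` (birth weight): mean(usual care) - mean(intervention),
    so a positive value always denotes a health gain (grams avoided).
    """
    iv = np.asarray(list(intervention_values), dtype=float)
    uv = np.asarray(list(usual_care_values), dtype=float)
    if iv.size == 0 or uv.size == 0:
        raise TrialDataError("both arms must be non-empty")
    if benefit_direction == "higher_is_better":
        return float(iv.mean() - uv.mean())
    if benefit_direction == "lower_is_better":
        return float(uv.mean() - iv.mean())
    raise TrialDataError(f"unknown benefit direction {benefit_direction!r}")
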