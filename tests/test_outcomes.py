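import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clustercea import (
    TrialDataError,
    TrialDataset,
    ValuationModel15D,
    effect_values,
    impute_15d,
    incremental_effect,
    score_15d,
)

from conftest import make_record


class TestScoring:
    def test_best_profile_scores_one(self, equal_model):
        assert score_15d([1] * 15, equal_model) == pytest.approx(1.0)

    def test_worst_profile_scores_zero(self, equal_model):
        assert score_15d([5] * 15, equal_model) == pytest.approx(0.0)

    def test_mixed_profile_hand_computed(self, equal_model):
        # fourteen dimensions at level 1 (value 1) and one at level 3 (value 0.5)
        levels = [1] * 14 + [3]
        assert score_15d(levels, equal_model) == pytest.approx((14 + 0.5) / 15)

    def test_fractional_level_interpolates(self, equal_model):
        levels = [1] * 14 + [1.5]
        assert score_15d(levels, equal_model) == pytest.approx((14 + 0.875) / 15)

    def test_missing_level_directs_to_imputation(self, equal_model):
        with pytest.raises(TrialDataError, match="impute"):
            score_15d([1] * 14 + [None], equal_model)

    def test_index_monotone_in_levels(self, equal_model):
        base = [2] * 15
        worse = [2] * 14 + [3]
        assert score_15d(worse, equal_model) < score_15d(base, equal_model)

    def test_model_round_trip(self, tmp_path, equal_model):
        path = tmp_path / "model.yml"
        equal_model.to_yaml(path)
        back = ValuationModel15D.from_yaml(path)
        assert np.allclose(back.weights, equal_model.weights)
        assert np.allclose(back.level_values, equal_model.level_values)

    def test_nonmonotone_model_rejected(self, equal_model):
        values = equal_model.level_values.copy()
        values[3, 2] = values[3, 1]  # flat step
        with pytest.raises(TrialDataError, match="decrease"):
            ValuationModel15D(weights=equal_model.weights, level_values=values)


def _impute_fixture(n_complete=40, missing_dims=(4,), seed=0, linear_in=2):
    """Complete cases where dim[d_miss] level value is an exact linear function
    of dim[linear_in]'s level value, plus one partially missing record."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_complete):
        levels = [float(rng.integers(1, 6)) for _ in range(15)]
        for d in missing_dims:
            levels[d] = levels[linear_in]  # same level -> same value, exact dependency
        recs.append(make_record(
            pid=f"c{i}", cluster="C1" if i % 2 else "C2",
            arm="usual_care" if i % 2 else "intervention",
            d15_baseline=levels, d15_followup=list(levels),
            age=25.0 + i, education_level=1 + i % 3, bmi=24.0 + (i % 7), married=bool(i % 2),
        ))
    probe = [float(rng.integers(1, 6)) for _ in range(15)]
    truth = {d: probe[linear_in] for d in missing_dims}
    for d in missing_dims:
        probe[d] = None
    recs.append(make_record(pid="probe", cluster="C1", arm="usual_care",
                            d15_baseline=probe, d15_followup=[1.0] * 15,
                            age=30.0, education_level=2, bmi=26.0, married=True))
    return TrialDataset(records=recs), truth


class TestImputation:
    def test_no_missing_is_identity(self, small_dataset, equal_model):
        out, log = impute_15d(small_dataset, equal_model)
        assert log.empty
        for a, b in zip(small_dataset.records, out.records):
            assert a.d15_baseline == b.d15_baseline
            assert a.d15_followup == b.d15_followup

    def test_exact_linear_dependency_recovered(self, equal_model):
        """A dimension that is a noiseless function of another is imputed exactly."""
        ds, truth = _impute_fixture()
        out, log = impute_15d(ds, equal_model)
        probe = next(r for r in out.records if r.participant_id == "probe")
        for d, level in truth.items():
            assert probe.d15_baseline[d] == pytest.approx(level, abs=1e-6)
        assert set(log["participant_id"]) == {"probe"}

    def test_seven_missing_dimensions_excluded_not_imputed(self, equal_model):
        ds, _ = _impute_fixture(missing_dims=tuple(range(7)))
        out, log = impute_15d(ds, equal_model)
        probe = next(r for r in out.records if r.participant_id == "probe")
        assert sum(1 for v in probe.d15_baseline if v is None) == 7
        assert log.empty

    def test_six_missing_dimensions_still_imputed(self, equal_model):
        ds, _ = _impute_fixture(missing_dims=tuple(range(6)))
        out, log = impute_15d(ds, equal_model)
        probe = next(r for r in out.records if r.participant_id == "probe")
        assert all(v is not None for v in probe.d15_baseline)
        assert len(log) == 6

    def test_imputation_is_idempotent(self, equal_model):
        ds, _ = _impute_fixture(missing_dims=(3, 8))
        once, _ = impute_15d(ds, equal_model)
        twice, log2 = impute_15d(once, equal_model)
        assert log2.empty
        for a, b in zip(once.records, twice.records):
            assert a.d15_baseline == b.d15_baseline

    def test_prediction_clipped_to_value_range(self, equal_model):
        ds, _ = _impute_fixture()
        out, log = impute_15d(ds, equal_model)
        assert ((log["predicted_value"] >= 0) & (log["predicted_value"] <= 1)).all()
        assert ((log["predicted_level"] >= 1) & (log["predicted_level"] <= 5)).all()

    def test_too_few_complete_cases_errors(self, equal_model):
        ds, _ = _impute_fixture(n_complete=10)
        with pytest.raises(TrialDataError, match="complete cases"):
            impute_15d(ds, equal_model)


class TestEffectValues:
    def test_vas_change_is_followup_minus_baseline(self, small_dataset):
        vals = effect_values(small_dataset, "vas_change").set_index("participant_id")
        assert vals.loc["p1", "value"] == pytest.approx(7.4 - 8.0)

    def test_missing_followup_excluded(self, small_dataset, equal_model):
        ds = TrialDataset(records=[copy.deepcopy(r) for r in small_dataset.records])
        ds.records[0].d15_followup = None
        vals = effect_values(ds, "d15_change", model=equal_model)
        assert "p1" not in set(vals["participant_id"])
        assert len(vals) == len(ds) - 1

    def test_birth_weight_passthrough(self, small_dataset):
        vals = effect_values(small_dataset, "birth_weight")
        assert len(vals) == len(small_dataset)
        assert vals["value"].min() > 0

    def test_unknown_measure_rejected(self, small_dataset):
        with pytest.raises(TrialDataError, match="apgar"):
            effect_values(small_dataset, "apgar")

    def test_per_outcome_analysis_sets_differ(self, default_trial, equal_model):
        """15D/VAS sets shrink by the follow-up missingness; birth weight barely."""
        ds, _ = default_trial
        n_bw = len(effect_values(ds, "birth_weight"))
        imputed, _ = impute_15d(ds, equal_model)
        n_15d = len(effect_values(imputed, "d15_change", model=equal_model))
        n_vas = len(effect_values(ds, "vas_change"))
        assert n_bw > n_15d and n_bw > n_vas
        # full follow-up missingness is ~11.8%, partials are imputed back in
        assert 0.80 < n_15d / len(ds) < 0.95


class TestIncrementalEffect:
    def test_birth_weight_benefit_signed(self):
        # arm means 3,521 vs 3,636 g -> +115 g avoided
        iv = [3521.0] * 4
        uv = [3636.0] * 4
        assert incremental_effect(iv, uv, "lower_is_better") == pytest.approx(115.0)

    def test_identical_means_give_zero(self):
        assert incremental_effect([1.0, 2.0], [1.5, 1.5], "higher_is_better") == 0.0

    def test_vas_change_difference(self):
        assert incremental_effect([-0.32], [-0.56], "higher_is_better") == pytest.approx(0.24)

    @settings(max_examples=30, deadline=None)
    @given(iv=st.lists(st.floats(-5, 5), min_size=1, max_size=8),
           uv=st.lists(st.floats(-5, 5), min_size=1, max_size=8))
    def test_antisymmetric_under_arm_swap_with_direction_flip(self, iv, uv):
        a = incremental_effect(iv, uv, "higher_is_better")
        b = incremental_effect(uv, iv, "lower_is_better")
        assert a == pytest.approx(b, abs=1e-9)
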