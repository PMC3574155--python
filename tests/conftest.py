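import pytest

from clustercea import (
    GeneratorParams,
    ParticipantRecord,
    TrialDataset,
    ValuationModel15D,
    default_unit_costs,
    generate_trial,
)


@pytest.fixture(scope="session")
def unit_costs():
    return default_unit_costs()


@pytest.fixture(scope="session")
def equal_model():
    return ValuationModel15D.equal_weights()


def make_record(pid="p1", cluster="C1", arm="usual_care", **kwargs):
    return ParticipantRecord(participant_id=pid, cluster_id=cluster, arm=arm, **kwargs)


@pytest.fixture
def small_dataset():
    """Two clusters per arm, six women, fully observed outcomes."""
    recs = []
    i = 0
    for arm, clusters in (("intervention", ("I1", "I2")), ("usual_care", ("U1", "U2"))):
        for cl in clusters:
            for _ in range(2 if cl in ("I1", "U1") else 1):
                i += 1
                recs.append(make_record(
                    pid=f"p{i}", cluster=cl, arm=arm,
                    visits_primary=10 + i, absence_days=i,
                    delivery_mode="vaginal", delivery_stay_days=3,
                    neonatal_stay_days=2,
                    birth_weight_g=3400.0 + 20 * i,
                    d15_baseline=[1.0] * 15,
                    d15_followup=[1.0] * 14 + [2.0],
                    vas_baseline_cm=8.0, vas_followup_cm=7.5 - 0.1 * i,
                    weight_gain_within_limits=(i % 2 == 0),
                    met_min_week_late=500.0 + 100 * i,
                    dietary_aims_met=i % 6,
                    age=30.0, education_level=2, bmi=26.0, married=True,
                ))
    return TrialDataset(records=recs)


@pytest.fixture(scope="session")
def default_trial():
    """One synthetic trial at the default study conditions."""
    ds, truth = generate_trial(GeneratorParams(seed=7))
    return ds, truth
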