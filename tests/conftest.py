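import pytest

from noggrisk import FraxProbabilities, Outcome, PatientProfile, anchor_table

# Published UK threshold anchors: {outcome: {age: (lat, it, uat, vhrt)}}.
PUBLISHED_ANCHORS = {
    Outcome.MOF: {
        50: (3.4, 7.3, 8.8, 11.7),
        55: (4.5, 9.5, 11.4, 15.2),
        60: (6.0, 12.2, 14.6, 19.4),
        65: (8.6, 16.5, 19.8, 26.4),
        70: (11.1, 20.3, 24.4, 32.5),
    },
    Outcome.HIP: {
        50: (0.23, 0.91, 1.1, 1.5),
        55: (0.43, 1.5, 1.7, 2.3),
        60: (0.80, 2.3, 2.8, 3.7),
        65: (1.4, 3.5, 4.2, 5.6),
        70: (2.6, 5.4, 6.5, 8.6),
    },
}


@pytest.fixture(scope="session")
def threshold_sets():
    return anchor_table()


@pytest.fixture
def neutral_profile():
    """A 70-year-old woman with no risk factors set."""
    return PatientProfile(age=70)


def make_probs(mof, hip, age=70.0, bmd=False, sex="female"):
    return FraxProbabilities(mof_pct=mof, hip_pct=hip, bmd_included=bmd, age=age, sex=sex)
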