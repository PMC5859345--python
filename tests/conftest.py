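import pytest

from warfarin_pgx.cohort import PatientRecord, TargetRange, Visit


@pytest.fixture
def make_patient():
    """Factory for a valid patient with overridable fields."""

    def _make(**overrides):
        defaults = dict(
            id="P001", sex="male", age=50.0, height=170.0, weight=70.0,
            race="white", enzyme_inducer=False, amiodarone=False,
            cyp2c9="*1/*1", vkorc1="GG", target_inr=TargetRange(2.0, 3.0),
            visits=(Visit(0, 35.0, inr=2.5),), bleeding="none",
            indication="thromboembolic",
        )
        defaults.update(overrides)
        return PatientRecord(**defaults)

    return _make


@pytest.fixture
def small_cohort(make_patient):
    """Three validated patients with distinct genotypes and visit histories."""
    return [
        make_patient(id="P001", cyp2c9="*1/*1", vkorc1="GG",
                     visits=tuple(Visit(i, 42.0, inr=2.4) for i in range(3))),
        make_patient(id="P002", sex="female", age=61.0, height=158.0, weight=72.0,
                     cyp2c9="*1/*2", vkorc1="GA", bleeding="minor",
                     indication="cardiovascular",
                     visits=tuple(Visit(i, 28.0, inr=2.1 + 0.1 * i) for i in range(4))),
        make_patient(id="P003", age=35.0, cyp2c9="*2/*2", vkorc1="AA",
                     bleeding="major", indication="both",
                     visits=(Visit(0, 49.0, inr=1.6), Visit(1, 35.0, inr=3.4))),
    ]
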