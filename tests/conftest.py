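import numpy as np
import pytest

from actikoa.records import ParticipantRecord
from actikoa.simulate import SyntheticConfig, generate_population
from actikoa.cohort import filter_valid


def make_record(
    id="P0",
    profile=None,
    month=6,
    sex="female",
    age=65.0,
    weight=85.0,
    bmi=31.0,
    codes=(),
    offset=None,
):
    if profile is None:
        profile = [20.0] * 24
    return ParticipantRecord(
        id=id,
        profile=tuple(float(v) for v in profile),
        month=month,
        sex=sex,
        age=age,
        weight=weight,
        bmi=bmi,
        icd10_codes=frozenset(codes),
        diagnosis_offset_years=offset,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One mid-sized synthetic cohort reused by read-only tests."""
    return generate_population(SyntheticConfig(n_participants=1200, seed=42))


@pytest.fixture(scope="session")
def eligible_cohort(small_cohort):
    kept, _ = filter_valid(small_cohort)
    return kept


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
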