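import numpy as np
import pytest

from nihlnet.audiograms import AAHLTable, Audiogram, Cohort, Individual, default_aahl_table
from nihlnet.features import FeatureSpec


@pytest.fixture(scope="session")
def aahl_table() -> AAHLTable:
    return default_aahl_table()


@pytest.fixture
def step_table() -> AAHLTable:
    """Tiny hand-made AAHL table with easy-to-interpolate values."""
    ages = [30, 40, 50, 60]
    values = np.array(
        [
            [0, 0, 0, 0, 0, 0],
            [2, 4, 6, 10, 10, 12],
            [4, 8, 12, 20, 20, 24],
            [6, 12, 18, 30, 30, 36],
        ],
        dtype=float,
    )
    return AAHLTable(ages, values)


def make_individual(
    ident: str = "X1",
    age: int = 50,
    right: dict | None = None,
    left: dict | None = None,
    group: str | None = None,
) -> Individual:
    flat = {f: 30.0 for f in (1, 2, 3, 4, 6, 8)}
    return Individual(
        id=ident,
        age=age,
        right=Audiogram(right or dict(flat)),
        left=Audiogram(left or dict(flat)),
        group=group,
    )


@pytest.fixture
def individual() -> Individual:
    return make_individual(
        right={1: 10, 2: 15, 3: 25, 4: 55, 6: 45, 8: 30},
        left={1: 15, 2: 15, 3: 35, 4: 65, 6: 55, 8: 40},
    )


@pytest.fixture
def tiny_cohort() -> Cohort:
    return Cohort(
        [
            make_individual("A", 35, group="control"),
            make_individual("B", 45, {1: 5, 2: 10, 3: 20, 4: 50, 6: 40, 8: 25}, group="exposed"),
            make_individual("C", 55),
        ],
        name="tiny",
    )


@pytest.fixture(scope="session")
def spec18() -> FeatureSpec:
    return FeatureSpec("AAHL+HTL-right+HTL-left")
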