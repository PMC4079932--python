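import numpy as np
import pytest

from hle import (
    AgeGrid,
    MortalityInput,
    build_abridged_life_table,
    classify,
    default_scenario,
    expected_mortality,
    generate_survey,
    true_values,
)


@pytest.fixture(scope="session")
def grid():
    return AgeGrid.default()


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def ground_truth(scenario):
    return true_values(scenario)


@pytest.fixture(scope="session")
def fixed_life_tables(scenario):
    """Noise-free life tables from the expected (rate x population) counts."""
    em = expected_mortality(scenario)
    return {sex: build_abridged_life_table(em[sex]) for sex in ("men", "women")}


@pytest.fixture(scope="session")
def survey(scenario):
    """One classified synthetic survey, shared across read-only tests."""
    return classify(generate_survey(scenario, seed=20240601))


@pytest.fixture()
def two_interval_table():
    """Hand-checkable table: intervals 60-64 and 65+, m = 0.02 and 0.1."""
    grid = AgeGrid([60, 65])
    mi = MortalityInput(grid, deaths=[20.0, 100.0], population=[1000.0, 1000.0], sex="men")
    return build_abridged_life_table(mi, radix=1.0)


def random_life_table(rng, grid=None, radix=1.0):
    """Arbitrary valid abridged life table with positive mortality."""
    if grid is None:
        grid = AgeGrid.default()
    k = len(grid)
    m = rng.uniform(0.005, 0.15, size=k)
    pop = rng.uniform(1_000, 50_000, size=k)
    mi = MortalityInput(grid, deaths=m * pop, population=pop)
    return build_abridged_life_table(mi, radix=radix)
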