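import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import malefert as mf

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def worked_example_table() -> mf.BirthTable:
    """One year, mothers aged 30: 1000 known-father births with 10% of them
    to fathers aged 33, plus 1000 births with the paternal age missing."""
    return mf.BirthTable.from_records(
        [
            (2000, 30, 30, 900.0),
            (2000, 30, 33, 100.0),
            (2000, 30, mf.UNKNOWN, 1000.0),
        ]
    )


@pytest.fixture
def constant_scenario() -> mf.ScenarioConfig:
    """Constant cohorts, srb 105, moderate gap; 3 years; expectation mode."""
    return mf.ScenarioConfig(years=(1990, 1992))


@pytest.fixture
def boom_bust_sizes() -> dict[int, float]:
    return {c: (120_000.0 if c < 1965 else 80_000.0) for c in range(1920, 2000)}
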