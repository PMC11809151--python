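import numpy as np
import pandas as pd
import pytest

from cohortsynth import (
    CohortSimConfig,
    DataTable,
    PanelSimConfig,
    VariableSchema,
    simulate_cohort,
    simulate_height_panel,
)


@pytest.fixture(scope="session")
def cohort_5000():
    """The default cross-sectional fixture at study scale."""
    table, truth = simulate_cohort(CohortSimConfig(n=5000, seed=11))
    return table, truth


@pytest.fixture(scope="session")
def cohort_small():
    table, truth = simulate_cohort(CohortSimConfig(n=400, seed=7))
    return table, truth


@pytest.fixture(scope="session")
def panel_2000():
    table, truth = simulate_height_panel(PanelSimConfig(n=2000, seed=5))
    return table, truth


@pytest.fixture
def toy_table():
    """Three mixed-type columns, no missing values."""
    df = pd.DataFrame({
        "age": [20.0, 30.0, 40.0, 50.0, 25.0, 35.0],
        "sex": ["m", "f", "f", "m", "m", "f"],
        "height": [170.0, 165.0, 160.0, 175.0, 172.0, 168.0],
    })
    return DataTable(df, (
        VariableSchema("age", "continuous"),
        VariableSchema("sex", "binary", ("m", "f")),
        VariableSchema("height", "continuous"),
    ))
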