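import numpy as np
import pandas as pd
import pytest

from dosegam import (CohortTable, SyntheticCohortConfig, ecdos_transform,
                     generate)


@pytest.fixture(scope="session")
def default_cohort() -> CohortTable:
    """The default synthetic cohort (seeded, ~2000 cells)."""
    return generate(SyntheticCohortConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort() -> CohortTable:
    """A small cohort for fast model fits."""
    cfg = SyntheticCohortConfig(
        seed=7,
        agex_bands=(0.0, 15.0, 30.0, 45.0),
        period_years=(1962.0, 1972.0, 1982.0, 1992.0),
        cutpoints=(0.0, 5.0, 20.0, 40.0, 70.0, 100.0),
        category_py_shares=(0.2, 0.35, 0.2, 0.1, 0.08, 0.07),
        expected_cases=3000.0,
    )
    return ecdos_transform(generate(cfg))


def toy_table(doses, obs=None, py=None, **extra) -> CohortTable:
    """Hand-rolled minimal cohort table for unit tests."""
    n = len(doses)
    year = np.full(n, 1980.0)
    age = np.linspace(50.0, 70.0, n)
    df = pd.DataFrame({
        "py": np.ones(n) if py is None else np.asarray(py, float),
        "obs": np.zeros(n, dtype=int) if obs is None else np.asarray(obs),
        "dose": np.asarray(doses, float),
        "age": age,
        "agex": age - (year - 1945.6),
        "year": year,
        "since": year - 1945.6,
        "birth": year - age,
        "logage": np.log(age),
        "city": "hiroshima",
        "distcat": "urban",
        "sex": "female",
    })
    for k, v in extra.items():
        df[k] = v
    return CohortTable(df=df)
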