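import numpy as np
import pandas as pd
import pytest

from cpgclock import builtin_clocks, default_config, predict_cohort, simulate_cohort
from cpgclock.io import CohortTable


@pytest.fixture(scope="session")
def clocks():
    return builtin_clocks()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (CG/NCO/CSSC demographics), fixed seed."""
    return simulate_cohort(default_config(seed=11))


@pytest.fixture(scope="session")
def default_deviations(default_cohort, clocks):
    devs, skipped = predict_cohort(default_cohort, clocks)
    assert not skipped
    return devs


@pytest.fixture()
def tiny_cohort():
    """Hand-built three-sample cohort with full marker data."""
    markers = {
        "ASPA_CpG1": [40.0, 30.0, 20.0],
        "EDARADD_CpG1": [45.0, 40.0, 30.0],
        "ELOVL2_CpG4": [30.0, 45.0, 68.0],
        "ELOVL2_CpG5": [32.0, 45.0, 65.0],
        "ELOVL2_CpG6": [35.0, 45.0, 63.0],
        "ELOVL2_CpG7": [35.0, 42.0, 58.0],
        "KLF14_CpG2": [10.0, 12.0, 18.0],
        "PDE4C_CpG1": [18.0, 25.0, 38.0],
        "TRIM59_CpG5": [25.0, 33.0, 52.0],
    }
    df = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "group": ["CG", "CG", "CSSC"],
            "sex": ["F", "M", "F"],
            "age_at_collection": [40.0, 60.0, 101.0],
            **markers,
        }
    )
    return CohortTable.from_dataframe(df)


def make_two_group_cohort(
    marker: str,
    n_a: int,
    n_b: int,
    sd_a: float,
    sd_b: float,
    rng: np.random.Generator,
    ages_a=(38.0, 65.0),
    ages_b=(100.0, 107.0),
) -> CohortTable:
    """Minimal single-marker cohort for dispersion tests."""
    rows = []
    for name, n, sd, (lo, hi) in (("A", n_a, sd_a, ages_a), ("B", n_b, sd_b, ages_b)):
        age = rng.uniform(lo, hi, n)
        meth = 20.0 + 0.3 * age + rng.normal(0.0, sd, n)
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{name}{i}",
                    "group": name,
                    "sex": "F",
                    "age_at_collection": age[i],
                    marker: float(np.clip(meth[i], 0, 100)),
                }
            )
    return CohortTable.from_dataframe(pd.DataFrame(rows))
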