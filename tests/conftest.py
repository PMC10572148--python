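import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from mpestack import default_spec_from_table1, generate_cohort, load_table2
from mpestack.markers import ALL_MARKERS


@pytest.fixture(scope="session")
def default_spec():
    return default_spec_from_table1()


@pytest.fixture(scope="session")
def cohort(default_spec):
    """One full-size synthetic cohort, shared across tests."""
    return generate_cohort(default_spec, seed=7)


@pytest.fixture(scope="session")
def table2():
    """The published 20-rung ladder fixture."""
    return load_table2()


@pytest.fixture()
def toy_cohort():
    """A tiny hand-sized cohort (6 MPE / 6 BPE) for exhaustive oracles."""
    rng = np.random.default_rng(42)
    n = 12
    rows = {
        "patient_id": [f"T{i:02d}" for i in range(n)],
        "group": ["MPE"] * 6 + ["BPE"] * 6,
        "age": rng.uniform(30, 80, n).round(1),
        "gender": list(np.where(rng.random(n) < 0.5, "male", "female")),
    }
    for j, m in enumerate(ALL_MARKERS):
        base = np.where(np.array(rows["group"]) == "MPE", 50.0, 5.0)
        rows[m] = base * rng.lognormal(0.0, 0.8, n)
    return pd.DataFrame(rows)
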