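import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dpasl import AcquisitionProtocol


@pytest.fixture(scope="session")
def proto():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def physio_grid():
    """Small (cbf, att, kw) grid spanning the physiological range."""
    cbf = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
    att = np.array([600.0, 1000.0, 1400.0, 1800.0, 2200.0])
    kw = np.array([0.0, 40.0, 110.0, 300.0, 800.0])
    return cbf, att, kw


@pytest.fixture()
def tiny_cohort():
    """Deterministic 24-row cohort with both sexes and races."""
    rng = np.random.default_rng(42)
    n = 24
    age = np.linspace(10, 90, n)
    sex = np.array(["M", "F"] * (n // 2))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "age": age,
            "sex": sex,
            "race": np.tile(["White", "Asian", "Latinx"], n // 3),
            "icv": rng.normal(1400, 100, n),
            "gm_density": rng.normal(0.55, 0.04, n),
            "y": 2.0 * age + 1.0,
        }
    )
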