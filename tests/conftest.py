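import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from streamtox import synth

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def mesocosm_clean():
    """Zero-noise mesocosm dataset: responses sit exactly on the curves."""
    return synth.gen_mesocosm(noise={"deterministic": True}, seed=0)


@pytest.fixture(scope="session")
def mesocosm_noisy():
    """Mesocosm dataset at the default noise settings."""
    return synth.gen_mesocosm(seed=42)


@pytest.fixture
def small_conc_table():
    """Two sites x four weeks x two compounds, one detection."""
    rows = []
    for site in ("A", "B"):
        for week in (1, 2, 3, 4):
            for compound in ("imidacloprid", "clothianidin"):
                detected = site == "A" and week == 2 and compound == "imidacloprid"
                rows.append({
                    "unit_id": site, "time": week, "compound": compound,
                    "concentration": 0.02 if detected else 0.0,
                    "reporting_level": 0.001, "censored": not detected,
                })
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
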