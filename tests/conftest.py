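import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lltproject import RegimenEffectTable, SimConfig, simulate_cohort

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def effect_table():
    return RegimenEffectTable()


@pytest.fixture(scope="session")
def small_cohort():
    """400 synthetic patients under the default study conditions."""
    return simulate_cohort(SimConfig(n_patients=400, seed=5))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Cohort with exact lab measurements (no assay noise)."""
    return simulate_cohort(SimConfig(n_patients=200, seed=9, lab_noise_sd=0.0))


def patients_frame(rows):
    """Build a minimal patients table from dicts, with defaults filled in."""
    defaults = dict(age=65.0, egfr=80.0, dialysis=0, death_day=np.nan)
    out = []
    for i, row in enumerate(rows):
        d = {"patient_id": i, **defaults, **row}
        out.append(d)
    return pd.DataFrame(out)
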