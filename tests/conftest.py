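import numpy as np
import pandas as pd
import pytest

from aptdki import default_cohort_config, default_offset_scheme, generate_cohort


@pytest.fixture(scope="session")
def scheme():
    return default_offset_scheme()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort, fixed seed, shared across tests."""
    return generate_cohort(default_cohort_config(), seed=0)


def records_from_2x2(n_pos_exposed, n_pos_unexposed, n_neg_exposed, n_neg_unexposed):
    """Expand 2x2 counts into a per-patient records table (x = exposure)."""
    rows = []
    for x, y, n in [
        (1, 1, n_pos_exposed), (0, 1, n_pos_unexposed),
        (1, 0, n_neg_exposed), (0, 0, n_neg_unexposed),
    ]:
        rows.extend([{"x": x, "lnm": y}] * n)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
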