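import numpy as np
import pandas as pd
import pytest

import strawtrack as st


@pytest.fixture(scope="session")
def paper_truth():
    """Truth at the study's generative parameters (16 pigs x 20 days scale)."""
    return st.default_truth(seed=0)


@pytest.fixture(scope="session")
def small_truth():
    return st.default_truth(seed=1, n_days=4)


@pytest.fixture(scope="session")
def small_hourly(small_truth):
    """4 pigs x 4 days complete grid from the generative model."""
    return st.simulate_hourly(small_truth, n_pigs=4, n_days=4, missing_prob=0.0, rng=7)


@pytest.fixture(scope="session")
def tiny_gappy():
    """2 pigs x 2 days with irregular observed hours (<= 16 rows): small
    enough for dense-matrix oracles, gappy enough to exercise rho**|dh|."""
    rng = np.random.default_rng(42)
    rows = []
    for pig in ["A", "B"]:
        for day in [1, 2]:
            hours = np.sort(rng.choice(24, size=rng.integers(3, 5), replace=False))
            for h in hours:
                rows.append((pig, day, int(h), float(rng.normal(800, 200))))
    return pd.DataFrame(rows, columns=["pig_id", "day", "hour", "dist_cm_per_h"])


@pytest.fixture(scope="session")
def calib_model():
    return st.PathLossModel(tx_power=-50.0, n=2.0)
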