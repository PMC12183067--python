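import numpy as np
import pandas as pd
import pytest

from ovafit import CohortConfig, LogisticDeclineParams, WeightedAgeSeries


@pytest.fixture
def small_series():
    """Fixed 7-point weighted rate series for oracle comparisons."""
    x = np.array([30.0, 32.0, 35.0, 38.0, 40.0, 42.0, 44.0])
    y = np.array([40.2, 39.5, 36.1, 28.0, 20.5, 12.3, 6.1])
    n = np.array([120, 340, 800, 1500, 1100, 600, 150])
    return WeightedAgeSeries(x, y, n)


@pytest.fixture
def cfg():
    return CohortConfig(seed=11)


@pytest.fixture
def svbt_raw():
    """Raw-shaped per-transfer cohort with a known monotone mechanism."""
    from scipy.special import expit

    from ovafit import logistic_decline

    rng = np.random.default_rng(321)
    n = 12_000
    ages = rng.integers(27, 46, n)
    grades = rng.choice(
        ["AA", "AB", "BA", "BB", "AC", "BC", "CB", "CA", "CC"],
        n, p=[0.2, 0.15, 0.15, 0.2, 0.05, 0.1, 0.1, 0.03, 0.02],
    )
    day = rng.choice([5, 6], n, p=[0.7, 0.3])
    base = logistic_decline(
        ages.astype(float), LogisticDeclineParams(55.0, 40.1, 3.02)
    ) / 100.0
    gmap = {"AA": 0, "AB": 1, "BA": 1, "BB": 2, "AC": 2, "BC": 3, "CB": 3,
            "CA": 2, "CC": 3}
    ordinal = np.array([gmap[g] for g in grades])
    lp = np.log(base / (1 - base)) - 0.33 * ordinal - 0.5 * (day == 6)
    y = (rng.random(n) < expit(lp)).astype(int)
    return pd.DataFrame(
        {"age": ages, "gardner": grades, "culture_day": day, "live_birth": y}
    )
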