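import dataclasses

import pytest

import physmig as pm


@pytest.fixture
def two_pref_panel() -> pm.PrefecturePanel:
    """Forced-arithmetic panel: licensing (100, 100), mean stocks (40, 60),
    actual increases (30, 70) -> national attrition 100, allocation (40, 60),
    net migrants (+30, -30)."""
    licensing_years = {1994 + k: 5.0 for k in range(1, 21)}  # 100 total each
    records = [
        pm.PrefectureRecord("A", {1994: 25.0, 2014: 55.0}, dict(licensing_years)),
        pm.PrefectureRecord("B", {1994: 25.0, 2014: 95.0}, dict(licensing_years)),
    ]
    return pm.PrefecturePanel(records, 1994, 2014)


def small_random_config(seed: int, **overrides) -> pm.SimulationConfig:
    """Small, fast, stochastic study conditions for property checks."""
    import numpy as np

    rng = np.random.default_rng(seed)
    base = pm.SimulationConfig(
        n_prefectures=int(rng.integers(3, 15)),
        baseline_year=2000,
        final_year=2000 + int(rng.integers(4, 13)),
        initial_stock_range=(200.0, 3000.0),
        licensing_rate_range=(10.0, 120.0),
        attrition_rate=float(rng.uniform(0.0, 0.05)),
        survey_interval=int(rng.integers(1, 4)),
        seed=seed,
    )
    return dataclasses.replace(base, **overrides)
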