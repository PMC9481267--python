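import numpy as np
import pandas as pd
import pytest

from plantarpress import CohortConfig, generate_cohort
from plantarpress.cohort import Trial


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort shared by plumbing tests: 8 subjects, 2 trials per
    condition (seed chosen so both outcome classes are present)."""
    config = CohortConfig(n_subjects=8, injured_fraction=0.35,
                          n_trials_per_condition=2, seed=11)
    store, profiles, roster = generate_cohort(config)
    return config, store, profiles, roster


@pytest.fixture
def make_trial():
    def _make(values, **kw):
        meta = dict(subject_id="S0", footwear="barefoot", gait="run",
                    foot="left", trial_index=0, measurement="mean_pressure",
                    zone="toe_1")
        meta.update(kw)
        return Trial(values=np.asarray(values, dtype=float), **meta)
    return _make


@pytest.fixture
def toy_feature_table():
    """60 subjects; one informative toe-1 peak-pressure feature plus noise
    features spread over several zones/measurements/footwear conditions so
    every group exclusion leaves enough candidates."""
    rng = np.random.default_rng(42)
    n = 60
    y = np.array([1] * 15 + [0] * 45)
    cols = {"toe_1|peak_pressure|barefoot|maximum": y * 2.0 + rng.normal(0, 0.5, n)}
    for j in range(10):
        cols[f"midfoot|mean_pressure|shod|fft_angle_{j}"] = rng.normal(0, 1, n)
        cols[f"metatarsal_4|mean_force|barefoot|fft_angle_{j}"] = rng.normal(0, 1, n)
        cols[f"whole_foot|vertical_force|shod|fft_magnitude_{j}"] = rng.normal(0, 1, n)
    df = pd.DataFrame(cols, index=[f"S{i:03d}" for i in range(n)])
    df["injured"] = y
    return df
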