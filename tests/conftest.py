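import numpy as np
import pandas as pd
import pytest

from lifecea.cohort import GeneratorConfig, apply_missingness, generate_cohort
from lifecea.imputation import ImputationConfig, impute_baseline, mice_impute
from lifecea.valuation import CrosswalkMap, default_value_set, value_utility_table


@pytest.fixture(scope="session")
def small_cohort():
    """A fully observed 400-patient trial used across modules."""
    cfg = GeneratorConfig(n_patients=400, seed=11)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def masked_cohort(small_cohort):
    cfg, data = small_cohort
    masked, masks = apply_missingness(data, cfg)
    return cfg, masked, masks


@pytest.fixture(scope="session")
def valued_masked(masked_cohort):
    cfg, data, masks = masked_cohort
    uv = value_utility_table(data.utilities, default_value_set("US"), CrosswalkMap())
    data2, uv2, _ = impute_baseline(data, uv)
    return cfg, data2, uv2


@pytest.fixture(scope="session")
def completed_small(valued_masked):
    cfg, data, uv = valued_masked
    icfg = ImputationConfig(m_utility=3, chained_iterations=3, seed=5)
    return data, uv, mice_impute(data, uv, icfg)


def toy_value_set():
    """Uniform 0.1-per-level-above-1 decrement, no interaction terms."""
    from lifecea.valuation import ValueSet
    from lifecea.cohort import EQ5D_DIMENSIONS

    dec = {(d, lv): 0.1 * (lv - 1) for d in EQ5D_DIMENSIONS for lv in (2, 3)}
    return ValueSet("toy-flat", dec)


@pytest.fixture()
def flat_value_set():
    return toy_value_set()


def make_profiles(n, rng=None, arm_split=True, **overrides):
    """A simple homogeneous end-of-trial profile table for microsim tests."""
    rng = rng or np.random.default_rng(0)
    base = {
        "arm": np.where(np.arange(n) % 2 == 0, "active", "control")
        if arm_split
        else np.repeat("control", n),
        "age": 60.0,
        "diabetes_duration": 10.0,
        "sex": "male",
        "base_utility": 0.8,
        "compliance": 1.0,
        "followup_years": 0.0,
        "hba1c": 8.0,
        "sbp": 135.0,
        "ldl": 2.3,
        "hdl": 1.1,
        "bmi": 32.0,
        "heart_rate": 72.0,
        "egfr": 76.0,
    }
    base.update(overrides)
    prof = pd.DataFrame(base, index=range(n))
    prof["patient_id"] = [f"S{i:05d}" for i in range(n)]
    return prof
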