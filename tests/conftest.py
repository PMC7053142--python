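import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from longbinrct import ScenarioConfig, generate_complete_replicate

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_trial() -> pd.DataFrame:
    """One fixed small complete replicate (N=60, moderate heterogeneity)."""
    cfg = ScenarioConfig(prevalence=0.3, rho=0.4, n_total=60, n_reps=1,
                         seed=0)
    rng = np.random.default_rng(12345)
    return generate_complete_replicate(cfg, cfg.beta_params, rng)


@pytest.fixture(scope="session")
def medium_replicate() -> pd.DataFrame:
    """One fixed replicate at the design size N=398, prevalence 0.1."""
    cfg = ScenarioConfig(prevalence=0.1, rho=0.3, n_reps=1, seed=0)
    rng = np.random.default_rng(2024)
    return generate_complete_replicate(cfg, cfg.beta_params, rng)
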