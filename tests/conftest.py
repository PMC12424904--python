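import numpy as np
import pandas as pd
import pytest

from pgsrisk.config import SimConfig, StratumSpec


def make_survival_table(
    durations, events, pgs=None, education=None, sex="female", birth_year=1950
) -> pd.DataFrame:
    """Minimal cohort table for direct survival-model tests."""
    n = len(durations)
    return pd.DataFrame(
        {
            "event_age": np.asarray(durations, dtype=float),
            "event_type": np.asarray(events, dtype=int),
            "pgs": np.zeros(n) if pgs is None else np.asarray(pgs, dtype=float),
            "education": ["low"] * n if education is None else list(education),
            "sex": [sex] * n if isinstance(sex, str) else list(sex),
            "birth_year": [birth_year] * n
            if np.isscalar(birth_year)
            else list(birth_year),
        }
    )


@pytest.fixture(scope="session")
def strata() -> StratumSpec:
    return StratumSpec()


@pytest.fixture(scope="session")
def null_sim_config() -> SimConfig:
    """All effect sizes zero; default hazards."""
    return SimConfig(
        n_per_study=5000, n_studies=1, seed=101,
        beta_pgs=0.0, beta_edu=0.0, beta_inter=0.0,
    )
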