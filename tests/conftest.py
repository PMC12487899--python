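import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from alediff.siler import SilerParams, sample_ages_at_death

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mammal_params() -> SilerParams:
    """Slow life history: low background hazard, late shallow senescence."""
    return SilerParams(a0=-2.0, a1=1.0, c=0.01, b0=-5.5, b1=0.15)


@pytest.fixture(scope="session")
def exponential_params() -> SilerParams:
    """Constant-hazard limit: juvenile and senescent terms suppressed."""
    return SilerParams(a0=-50.0, a1=1.0, c=0.02, b0=-50.0, b1=1e-6)


def make_records(params, alpha, n, seed, species="sp1", sex="female", censor_frac=0.0):
    """Record table of simulated deaths (optionally part-censored)."""
    rng = np.random.default_rng(seed)
    deaths = sample_ages_at_death(params, alpha, n, rng)
    event = np.full(n, "death", dtype=object)
    end = deaths.copy()
    n_cens = int(round(censor_frac * n))
    if n_cens:
        idx = rng.choice(n, n_cens, replace=False)
        event[idx] = "censored"
        end[idx] = alpha + rng.uniform(size=n_cens) * (deaths[idx] - alpha)
        end[idx] = np.maximum(end[idx], alpha + 1e-6)
    return pd.DataFrame(
        {
            "species": species,
            "sex": sex,
            "entry_age": float(alpha),
            "end_age": end,
            "event": event,
        }
    )


@pytest.fixture(scope="session")
def death_records(mammal_params):
    return make_records(mammal_params, alpha=2.0, n=800, seed=42)
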