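import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dyadseq as dq

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


def make_series(columns: dict[str, list[int]], dyad_id: str = "d1") -> dq.BehaviorSeries:
    """Build a BehaviorSeries from explicit per-category 0/1 columns."""
    return dq.BehaviorSeries(dyad_id, pd.DataFrame(columns))


@pytest.fixture
def scheme() -> dq.CodingScheme:
    return dq.mcam_scheme()


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture(scope="session")
def mcam_sample() -> dq.SyntheticSample:
    """A default-world synthetic sample (54 dyads, T=90, MCAM rates)."""
    return dq.generate_sample(dq.default_config(seed=123))


@pytest.fixture(scope="session")
def mcam_profiles(mcam_sample) -> list[dq.DyadProfile]:
    return [dq.dyad_profile(s) for s in mcam_sample.series]


def random_series(rng: np.random.Generator, T: int, k: int = 2,
                  dyad_id: str = "d1") -> dq.BehaviorSeries:
    cols = {f"B{j}": rng.integers(0, 2, T).tolist() for j in range(k)}
    return make_series(cols, dyad_id)
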