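import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dnmcross.datasets import cross_disorder_count_table

settings.register_profile(
    "default",
    settings(
        max_examples=60,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def published_counts():
    """The bundled cross-disorder DNM class-count table (six cohorts + control)."""
    return cross_disorder_count_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
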