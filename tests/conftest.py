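import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rootarray as ra

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_design():
    """Two stages x two replicates."""
    return pd.DataFrame(
        {"stage": ["10", "10", "15", "15"], "replicate": [1, 2, 1, 2]},
        index=["10D_r1", "10D_r2", "15D_r1", "15D_r2"],
    )


@pytest.fixture
def small_em(small_design):
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(10, 1, (6, 4)),
        index=[f"P{i}" for i in range(6)],
        columns=small_design.index,
    )
    return ra.ExpressionMatrix(values, small_design)


@pytest.fixture
def scaled_counts():
    """The default planted composition scaled down 10x (min 2 per class)."""
    return {k: max(2, v // 10) for k, v in ra.study_class_counts().items()}


@pytest.fixture
def noiseless_sim(scaled_counts):
    return ra.SimulationConfig(class_counts=scaled_counts, replicate_sd=0.0,
                               seed=11)
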