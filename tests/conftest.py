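import numpy as np
import pytest

from ebpi import EffectPanel


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def worked_panel():
    """Three-factor panel with beta = (0, 1, 2) and all variances 0.5."""
    return EffectPanel(
        labels=["x1", "x2", "x3"],
        beta=np.array([0.0, 1.0, 2.0]),
        se=np.sqrt(np.full(3, 0.5)),
    )


@pytest.fixture
def random_panel(rng):
    k = 40
    se = np.sqrt(rng.uniform(0.25, 0.75, size=k))
    beta = rng.normal(0.0, 1.0, size=k) + rng.normal(0.0, se)
    return EffectPanel(labels=[f"v{i}" for i in range(k)], beta=beta, se=se)
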