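import numpy as np
import pandas as pd
import pytest

from omicnet.containers import make_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def groups6v6():
    """Standard 6-vs-6 group labels matching the simulator's sample names."""
    samples = [f"control_{i}" for i in range(1, 7)] + [f"case_{i}" for i in range(1, 7)]
    return pd.Series(["control"] * 6 + ["case"] * 6, index=samples)


def random_log2_matrix(rng, n_features=20, n_samples=12, layer="protein"):
    samples = [f"control_{i}" for i in range(1, n_samples // 2 + 1)] + [
        f"case_{i}" for i in range(1, n_samples - n_samples // 2 + 1)
    ]
    vals = pd.DataFrame(
        20 + rng.standard_normal((n_features, n_samples)),
        index=[f"F{i:03d}" for i in range(n_features)],
        columns=samples,
    )
    return make_matrix(vals, layer=layer, scale="log2")
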