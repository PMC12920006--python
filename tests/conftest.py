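import numpy as np
import pandas as pd
import pytest

from aretree import (
    ContinuousDGPSpec,
    DiscreteDGPSpec,
    MixtureDataset,
    NullDGPSpec,
    generate,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture(scope="session")
def null_data_small():
    return generate(NullDGPSpec(), 500, 11)


@pytest.fixture(scope="session")
def continuous_data():
    return generate(ContinuousDGPSpec(), 2000, 7)


@pytest.fixture(scope="session")
def discrete_data():
    return generate(DiscreteDGPSpec(), 2000, 5)


@pytest.fixture()
def step_data():
    """Strong single-threshold outcome: Y jumps by 10 when A1 <= 2."""
    rng = np.random.default_rng(3)
    n = 500
    W = pd.DataFrame({"W1": rng.normal(0, 1, n)})
    A = pd.DataFrame(
        {"A1": np.round(rng.uniform(0, 4, n), 1), "A2": np.round(rng.normal(0, 1, n), 1)}
    )
    Y = 10.0 * (A["A1"].to_numpy() <= 2.0) + rng.normal(0, 0.1, n)
    return MixtureDataset(W, A, Y)
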