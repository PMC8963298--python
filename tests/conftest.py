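import warnings

import numpy as np
import pandas as pd
import pytest

from metaboqc import AbundanceMatrix, PipelineConfig
from metaboqc.simulate import generate_fixture


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def random_matrix(seed: int, n: int = 20, p: int = 10, miss: float = 0.15) -> AbundanceMatrix:
    """Seeded random matrix with missing entries for oracle comparisons."""
    rng = np.random.default_rng(seed)
    vals = np.exp(rng.normal(1.0, 0.5, size=(n, p)))
    mask = rng.random((n, p)) < miss
    vals = np.where(mask, np.nan, vals)
    return AbundanceMatrix(
        pd.DataFrame(
            vals,
            index=[f"s{i}" for i in range(n)],
            columns=[f"f{j}" for j in range(p)],
        )
    )


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic dataset (200 x 60, 3 blocks, seed 1)."""
    return generate_fixture(seed=1)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(exclude_derived=True)
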