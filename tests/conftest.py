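import numpy as np
import pandas as pd
import pytest

from claudinlow.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_matrix(rng):
    """Random 30 x 12 expression matrix with a couple of missing cells."""
    m = pd.DataFrame(
        rng.normal(size=(30, 12)),
        index=[f"g{i:02d}" for i in range(30)],
        columns=[f"s{j:02d}" for j in range(12)],
    )
    m.iloc[3, 4] = np.nan
    m.iloc[17, 0] = np.nan
    return m


@pytest.fixture
def fast_cfg():
    """Default-structure synthetic config with a reduced null background."""
    return SyntheticConfig(seed=7, n_null_genes=200)
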