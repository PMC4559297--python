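import numpy as np
import pandas as pd
import pytest

from dmi.simulate import generate_dataset, preset_spec


@pytest.fixture(scope="session")
def d1_data():
    """One D1 benchmark instance shared across tests (seed 1)."""
    return generate_dataset(preset_spec("d1", seed=1))


@pytest.fixture(scope="session")
def independent_matrix():
    """A fully independent expression matrix: 150 genes x 100 samples."""
    rng = np.random.default_rng(11)
    return pd.DataFrame(
        rng.normal(size=(150, 100)),
        index=[f"G{i:03d}" for i in range(150)],
        columns=[f"S{j:03d}" for j in range(100)],
    )
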