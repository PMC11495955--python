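import numpy as np
import pandas as pd
import pytest

import ceeresponse as cr


@pytest.fixture(scope="session")
def schedule():
    """Standard CEE schedule: three 10 min phases in 5 s blocks."""
    return cr.make_phase_schedule(600, 600, 600, 5)


@pytest.fixture(scope="session")
def toy_poisson_series():
    """Nine-block Poisson series with an evident exposure enhancement."""
    vals = [1.0, 1.0, 2.0, 6.0, 7.0, 7.0, 2.0, 1.0, 1.0]
    phases = ["pre"] * 3 + ["exp"] * 3 + ["post"] * 3
    return pd.DataFrame(
        {
            "block_index": np.arange(9),
            "phase": phases,
            "value": vals,
            "observed": True,
        }
    )


@pytest.fixture(scope="session")
def toy_poisson_fit(toy_poisson_series):
    """A long, well-mixed fit of the toy series, shared across tests."""
    model = cr.LatentStateModel(
        "poisson", n_samples=30_000, n_burnin=20_000, n_chains=3, seed=17
    ).fit(toy_poisson_series)
    return model
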