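import numpy as np
import pytest

import trajgrn as tg
from trajgrn.gp_smooth import SmoothedCurves
from trajgrn.synthetic_data import default_spec, example_cascade_spec


@pytest.fixture(scope="session")
def profiles_dataset():
    """Default desk-scale synthetic dataset (500 cells x 12 genes)."""
    return tg.generate_profiles(default_spec(seed=1))


@pytest.fixture(scope="session")
def shifted(profiles_dataset):
    return tg.shift_to_nonnegative(profiles_dataset.matrix)


@pytest.fixture(scope="session")
def embedding(shifted):
    return tg.DiffusionMap(n_components=3).fit_transform(shifted.values.T)


@pytest.fixture(scope="session")
def trajectory(embedding):
    return tg.order_cells(embedding, seed=1)


@pytest.fixture(scope="session")
def cascade():
    """3-gene cascade ODE model with its noise-free observation curves."""
    spec = example_cascade_spec()
    n_cells = 200
    ds = tg.generate_from_ode(spec, n_cells, x0=[0.5, 0.5, 0.5], seed=0,
                              shuffled=False)
    obs = SmoothedCurves(
        grid=np.arange(n_cells, dtype=float),
        mean=ds.noiseless,
        variance=np.zeros_like(ds.noiseless),
        gene_ids=list(spec.gene_ids),
    )
    return spec, obs
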