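import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

import heliforge as hf
from heliforge.synthetic_oracle import default_params, generate_dataset


@pytest.fixture(scope="session")
def noiseless_params():
    return default_params(noise=False)


@pytest.fixture(scope="session")
def small_pool():
    """A 300-row halogen+EWG pool for fast local-model tests."""
    params = default_params()
    ds = generate_dataset(150, family="halogen", max_subs=3, params=params, seed=11)
    ds = ds.append(generate_dataset(180, family="EWG", max_subs=3, params=params, seed=12))
    return ds.subset(range(300))


@pytest.fixture(scope="session")
def fast_forest():
    """Forest hyper-parameters small enough for unit tests."""
    return {"n_estimators": 30}


@pytest.fixture
def parent():
    return hf.HeliceneMolecule.parent()
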