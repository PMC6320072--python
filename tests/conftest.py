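import numpy as np
import pytest

from planergy.synth import GeneratorConfig


@pytest.fixture(scope="session")
def cfg():
    """Default study conditions, fixed seed."""
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return GeneratorConfig(seed=1, cv_mass=0.0, cv_rate=0.0,
                           cv_composition=0.0)


@pytest.fixture(scope="session")
def data_dir(tmp_path_factory, cfg):
    """A full synthetic data directory (smallish sizes, shared)."""
    from planergy.synth import write_all_tables

    d = tmp_path_factory.mktemp("synthdata")
    write_all_tables(cfg, d, n_animals=80, n_vials=80, n_growth=30,
                     n_degrowth=45, n_assay=50, n_bomb=40)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
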