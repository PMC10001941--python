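import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from grdf.cascade import CascadeConfig
from grdf.encoders import featurize
from grdf.fegs import load_default_property_table
from grdf.synthetic import SimConfig, gen_peptides, gen_property_table

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_table():
    """A 3-row synthetic property table for fast FEGS tests."""
    return gen_property_table(3, seed=11)


@pytest.fixture(scope="session")
def default_table():
    return load_default_property_table()


@pytest.fixture(scope="session")
def tiny_cascade_config():
    """A cheap cascade configuration for unit tests."""
    return CascadeConfig(n_forests=1, n_trees=10, crossfit_folds=2, max_levels=3, seed=0)


@pytest.fixture(scope="session")
def separable_xy():
    """Small separable synthetic problem featurised with a small table."""
    peps = gen_peptides(SimConfig(n_per_class=40, effect=0.5, seed=3))
    table = gen_property_table(3, seed=11)
    X, names, block_index = featurize(peps, table)
    y = np.array([p.label for p in peps])
    return X, y, names, block_index


@pytest.fixture(scope="session")
def separable_full_xy():
    """Full-pipeline featurisation of the separable study fixture
    (200 peptides per class, composition bias 0.5 plus planted motif)."""
    peps = gen_peptides(SimConfig(n_per_class=200, effect=0.5, seed=1))
    X, names, block_index = featurize(peps, load_default_property_table())
    y = np.array([p.label for p in peps])
    return X, y, names, block_index
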