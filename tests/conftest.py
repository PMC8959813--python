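import numpy as np
import pytest

from tlscrown.synthetic_stand import TreeModel, generate_tree, oracle_traits


@pytest.fixture(scope="session")
def dense_tree():
    """One dense, noiseless conical-stem tree: model, cloud, oracle traits.

    Session-scoped because sampling ~200k points and computing oracle traits
    is shared by the classification, taper and trait-recovery tests.
    """
    model = TreeModel(
        height=20.0, d0=0.25, taper_exponent=1.0,
        crown_shape="ellipsoid", crown_base=9.0, crown_radius=2.0,
        crown_max_height=11.75, crown_density=2000.0, stem_density=1500.0,
        noise_sd=0.0,
    )
    cloud = generate_tree(model, seed=7, ground_radius=0)
    return model, cloud, oracle_traits(model)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
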