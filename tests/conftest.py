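import pytest

from tdmdscreen import simkit


@pytest.fixture(scope="session")
def small_cfg():
    """A small multi-family panel: one 3-member family plus singletons."""
    return simkit.SimConfig(
        seed=7, n_families=6, family_sizes=(3, 1, 1, 1, 1, 1), depth=2e5
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return simkit.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def screen_cfg():
    """A screen-sized panel of singleton loci for DE / BBUM behaviour."""
    return simkit.SimConfig(
        seed=11,
        n_families=400,
        family_sizes=(1,) * 400,
        frac_sensitive=0.1,
        depth=2e6,
    )


@pytest.fixture(scope="session")
def screen_data(screen_cfg):
    return simkit.simulate_dataset(screen_cfg)
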