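import pytest

from splicescreen.simulate import SimConfig, generate_bundles


@pytest.fixture(scope="session")
def default_cfg():
    """The default study conditions: 15 types, 60T/30N, planted +0.2 shift."""
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def default_study(default_cfg):
    return generate_bundles(default_cfg)


@pytest.fixture(scope="session")
def small_cfg():
    """A down-scaled study for fast structural tests."""
    return SimConfig(
        n_cancer_types=4,
        planted_n_types=3,
        n_tumor=24,
        n_normal=12,
        n_paired=12,
        n_genes=6,
        n_events_per_gene=2,
        n_factors=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_bundles(small_cfg)
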