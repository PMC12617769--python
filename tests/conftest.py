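import pytest

from trinet import simulate as sim


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down study design: full group layout, fewer features."""
    return sim.SimConfig(
        n_mrna=500,
        n_mirna=60,
        n_protein=100,
        n_true_triplets=8,
        decoy_targets_per_mirna=60,
        n_modules=2,
        module_size=60,
        markers_per_type=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return sim.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def null_cfg():
    """No planted structure, equal size factors: clean null data."""
    return sim.SimConfig(
        n_mrna=2500,
        n_mirna=50,
        n_protein=50,
        de_fraction=0.0,
        n_true_triplets=0,
        n_modules=0,
        markers_per_type=0,
        decoy_targets_per_mirna=10,
        size_factor_range=(1.0, 1.0),
        seed=5,
    )
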