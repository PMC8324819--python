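import pytest

from fpinv import (DerivativeOperators, TrainConfig, build_grid, example_spec,
                   make_dataset)


@pytest.fixture(scope="session")
def unit_grid():
    """11 bins on [0, 1] — small enough for brute-force oracles."""
    return build_grid(0.0, 1.0, 11)


@pytest.fixture(scope="session")
def unit_ops(unit_grid):
    return DerivativeOperators.build(unit_grid)


@pytest.fixture(scope="session")
def flux_spec():
    return example_spec("flux")


@pytest.fixture(scope="session")
def flux_ops(flux_spec):
    return DerivativeOperators.build(flux_spec.grid)


@pytest.fixture(scope="session")
def small_flux_dataset():
    """A reduced flux dataset (12 sequences of 20 frames) for fast training
    tests; the full-size study conditions live in the acceptance tests."""
    return make_dataset("flux", n_sequences=12, n_times=20, n_train=8, seed=3)


@pytest.fixture(scope="session")
def small_flux_trained(small_flux_dataset, flux_ops):
    from fpinv import train

    cfg = TrainConfig(n=2, max_iterations=40)
    state = train(small_flux_dataset, cfg, flux_ops)
    return small_flux_dataset, cfg, state
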