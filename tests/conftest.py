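import numpy as np
import pytest

from heterokern.data_model_io import build_examples
from heterokern.kernels import KernelInputs
from heterokern.synthetic_data import SimulationParams, simulate


def small_params(seed: int = 0, **overrides) -> SimulationParams:
    """Desk-scale generator parameters for fast kernel/CV tests."""
    defaults = dict(
        n_proteins=70,
        n_domains=30,
        n_templates=4,
        n_positive_pairs=8,
        n_large_complexes=6,
        complex_size_min=3,
        complex_size_max=4,
        background_edge_prob=0.05,
        n_genomes=12,
        n_localizations=5,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


def small_instance(seed: int = 0, **overrides):
    """(inputs, pairset) from a small synthetic dataset."""
    net, tables, catalog, _ = simulate(small_params(seed, **overrides))
    inputs = KernelInputs(net, *tables)
    return inputs, build_examples(net, catalog)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-parameter synthetic dataset shared across tests."""
    net, tables, catalog, truth = simulate(SimulationParams(seed=7))
    return net, tables, catalog, truth


@pytest.fixture(scope="session")
def default_instance(default_bundle):
    net, tables, catalog, _ = default_bundle
    return KernelInputs(net, *tables), build_examples(net, catalog)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
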