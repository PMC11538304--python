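import numpy as np
import pytest

from migtensor import PlantedSpec, benchmark, fit_ncpd, generate
from migtensor.io import FlowTensor, GeoIndex


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_tensor(rng):
    """A 4x4x3 integer flow tensor with the diagonal masked."""
    values = rng.integers(0, 20, size=(4, 4, 3)).astype(float)
    mask = np.ones_like(values)
    idx = np.arange(4)
    mask[idx, idx, :] = 0.0
    geo = GeoIndex.from_labels(["a", "b", "c", "d"])
    return FlowTensor(values=values, mask=mask, geo=geo, periods=(2000, 2001, 2002))


@pytest.fixture(scope="session")
def noiseless_planted():
    """Default-scale planted tensor without noise: 30 geos, 29 periods, 3 systems."""
    spec = PlantedSpec(noise="none", seed=42)
    tensor, truth = generate(spec)
    return tensor, truth


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_planted):
    tensor, _ = noiseless_planted
    return fit_ncpd(tensor, 3, seed=7, n_restarts=10)


@pytest.fixture(scope="session")
def poisson_benchmark():
    """20 seeded generate-fit-score replicates of the default Poisson benchmark."""
    spec = PlantedSpec(seed=0)
    return benchmark(spec, n_replicates=20, seed=20240)
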