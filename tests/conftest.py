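import numpy as np
import pytest

from opermorph import LandmarkConfiguration, reflect
from opermorph.simulate import SimulationConfig, generate_dataset


@pytest.fixture()
def rng():
    # fresh deterministic generator per test: results do not depend on
    # which other tests ran first
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared across tests."""
    cfg = SimulationConfig(
        n_species=6,
        n_specimens_per_species=3,
        k_landmarks=40,
        seed=11,
        habitat_effect=0.1,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_aligned(small_dataset):
    """Reflected + slid-and-aligned version of the small dataset."""
    from opermorph import slide_and_align

    configs = [
        reflect(c) if meta["ID"].endswith("right") else c
        for c, meta in small_dataset.configs
    ]
    aligned = slide_and_align(configs)
    ids = [m["ID"].rsplit("_", 1)[0] for _, m in small_dataset.configs]
    sides = [m["ID"].rsplit("_", 1)[1] for _, m in small_dataset.configs]
    return aligned, ids, sides


def random_config(rng, k=20):
    """A generic non-degenerate landmark configuration."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, k))
    r = 1.0 + 0.2 * rng.standard_normal(k)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return LandmarkConfiguration(pts)
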