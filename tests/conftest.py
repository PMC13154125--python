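import numpy as np
import pytest

from xtalgroup.synthetic_data import (
    default_config,
    fixture_geometries,
    generate_dataset,
)

DEFAULT_MARGINAL_10_UNIFORM = {
    sg: 0.1 for sg in (1, 2, 4, 14, 15, 19, 29, 33, 61, 96)
}


@pytest.fixture(scope="session")
def fixtures_by_name():
    return {f.name: f for f in fixture_geometries()}


@pytest.fixture(scope="session")
def small_dataset():
    """~300 records from the documented planted-rule conditions (small library)."""
    cfg = default_config(seed=11, n_molecules=300)
    cfg.library_size = 80
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def random_clusters():
    """Random small atom clusters (generically asymmetric) for oracle checks."""
    rng = np.random.default_rng(202)
    clusters = []
    pool = ["C", "C", "N", "O", "H", "H", "S", "C", "N", "O"]
    for _ in range(20):
        n = int(rng.integers(3, 9))
        elements = list(rng.choice(pool, size=n))
        coords = rng.uniform(-2.5, 2.5, size=(n, 3))
        clusters.append((elements, coords))
    return clusters
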