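import numpy as np
import pytest

from stgwr.pca import fit_pca, standardize
from stgwr.synthetic import (COVARIATE_COLUMNS, generate_covariate_panel,
                             generate_station_network)


@pytest.fixture(scope="session")
def big_panel():
    """Default-config panel at study scale (57 stations x 88 dates ~ 5000)."""
    stations = generate_station_network(57, seed=1)
    return generate_covariate_panel(stations, 88, seed=2)


@pytest.fixture(scope="session")
def big_pca(big_panel):
    Z, means, sds = standardize(big_panel, COVARIATE_COLUMNS)
    return Z, fit_pca(Z, columns=COVARIATE_COLUMNS)


@pytest.fixture(scope="session")
def benchmarks():
    """AICc-selected fits of all four families in each heterogeneity regime."""
    from stgwr.benchmark import run_recovery_benchmark
    return {preset: run_recovery_benchmark(preset, seed=11)
            for preset in ("space-only", "time-only", "space-time")}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
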