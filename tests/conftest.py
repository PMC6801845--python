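import numpy as np
import pandas as pd
import pytest

import gravscreen as gs
from gravscreen.normalize import effective_library_sizes, normalize, tmm_factors


@pytest.fixture(scope="session")
def default_fixture():
    """Default synthetic experiment (seed 0): counts, design, truth, gene sets."""
    counts, design, truth, gene_sets = gs.simulate_fixture(seed=0)
    return counts, design, truth, gene_sets


@pytest.fixture(scope="session")
def normalized_fixture(default_fixture):
    """Normalization products + estimated dispersion for the default fixture."""
    counts, design, truth, _ = default_fixture
    factors = tmm_factors(counts)
    norm = normalize(counts, factors)
    lib = effective_library_sizes(counts, factors)
    groups = design.set_index("sample_id")["condition"]
    phi = gs.estimate_common_dispersion(counts, groups, lib_sizes=lib).phi
    return norm, factors, lib, phi


@pytest.fixture(scope="session")
def screen_result(default_fixture, normalized_fixture):
    counts, design, truth, _ = default_fixture
    norm, factors, lib, phi = normalized_fixture
    config = gs.ScreenConfig(panel=tuple(truth.index[truth["in_panel"]]))
    return gs.run_screen(counts, norm, design, config, phi, lib_sizes=lib)


@pytest.fixture()
def toy_counts():
    """5-gene, 3-sample toy count matrix with a pure depth difference in s2."""
    return pd.DataFrame(
        {
            "s0": [100, 200, 300, 50, 10],
            "s1": [110, 180, 310, 55, 12],
            "s2": [200, 400, 600, 100, 20],
        },
        index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"),
    )


def nb_counts(rng, mu, phi, n):
    """Reference NB sampler for test data (gamma-Poisson mixture)."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if phi == 0:
        return rng.poisson(np.repeat(mu[:, None], n, axis=1))
    lam = rng.gamma(1.0 / phi, phi * mu[:, None], size=(mu.size, n))
    return rng.poisson(lam)
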