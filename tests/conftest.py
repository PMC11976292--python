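import numpy as np
import pandas as pd
import pytest

from methylhet.simulate import SimulationConfig, simulate_epiallele_data


@pytest.fixture(scope="session")
def small_sim():
    """A small two-group epiallele dataset shared across tests."""
    cfg = SimulationConfig(
        seed=42, n_eloci=200, n_patients=3, regions_per_patient=3, n_normal=5,
        frac_differential=0.25,
    )
    return simulate_epiallele_data(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_count_vectors(rng, n, max_depth=200):
    """Random 16-pattern count vectors with positive depth."""
    out = []
    while len(out) < n:
        alpha = rng.uniform(0.1, 5.0)
        p = rng.dirichlet(np.full(16, alpha))
        depth = int(rng.integers(1, max_depth))
        c = rng.multinomial(depth, p)
        out.append(c)
    return np.array(out)
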