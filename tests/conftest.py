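"""Shared fixtures: small graphs and planted compendia with known answers."""

import numpy as np
import pandas as pd
import pytest

from gcnbench.network import Network
from gcnbench.simulate import SimulationConfig, simulate_expression


@pytest.fixture
def two_triangle_bridge() -> Network:
    """Two triangles joined by one bridge edge; the natural 3+3 split has
    modularity Q = 2*(3/7 - (7/14)^2) = 5/14."""
    net = Network()
    for a, b in [("a", "b"), ("b", "c"), ("a", "c"),
                 ("d", "e"), ("e", "f"), ("d", "f"),
                 ("c", "d")]:
        net.add_edge(a, b)
    return net


@pytest.fixture
def two_triangles_disconnected() -> Network:
    net = Network()
    for a, b in [("a", "b"), ("b", "c"), ("a", "c"),
                 ("d", "e"), ("e", "f"), ("d", "f")]:
        net.add_edge(a, b)
    return net


def planted_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Clean 4 x 25 planted compendium (no contamination) used across tests."""
    fields = dict(
        n_modules=4, genes_per_module=25, n_background=0,
        n_conditions=60, n_replicates=1, within_module_cor=0.8,
        frac_noisy_genes=0.0, frac_low_signal=0.0, seed=seed,
    )
    fields.update(overrides)
    return SimulationConfig(**fields)


@pytest.fixture
def planted_matrix():
    matrix, design, truth = simulate_expression(planted_config(seed=11))
    return matrix, design, truth


@pytest.fixture
def chain3_sampler():
    """Sampler for the 3-gene chain with precision [[1,.4,0],[.4,1,.4],[0,.4,1]];
    true partial correlations are -0.4 (1-2), -0.4 (2-3), 0 (1-3)."""
    omega = np.array([[1.0, 0.4, 0.0], [0.4, 1.0, 0.4], [0.0, 0.4, 1.0]])
    sigma = np.linalg.inv(omega)

    def draw(seed: int, n: int = 500) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        x = rng.multivariate_normal(np.zeros(3), sigma, size=n)
        return pd.DataFrame(x.T, index=["A", "B", "C"],
                            columns=[f"s{i}" for i in range(n)])

    return draw
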