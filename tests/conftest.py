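import numpy as np
import pytest

from compmaxent import CMEParameters, CompositionTable, TildeParameters


def random_refined(rng, n, h_scale=1.0, k_scale=2.0) -> CMEParameters:
    """Random valid refined parameters (symmetric K, zero diag, h_N = 0)."""
    k = rng.normal(0.0, k_scale, (n, n))
    k = 0.5 * (k + k.T)
    np.fill_diagonal(k, 0.0)
    h = rng.normal(0.0, h_scale, n)
    h[-1] = 0.0
    return CMEParameters(h=h, K=k)


def random_tilde(rng, n, scale=2.0) -> TildeParameters:
    """Random (generally asymmetric) tilde parameters."""
    m = n - 1
    return TildeParameters(
        h_tilde=rng.normal(0.0, scale, m),
        K_tilde=rng.normal(0.0, scale, (m, m)),
        n_components=n,
    )


def random_table(rng, d, n, conc=1.0) -> CompositionTable:
    """Dirichlet-distributed composition table."""
    return CompositionTable(
        rng.dirichlet(np.full(n, conc), size=d),
        [f"c{i + 1}" for i in range(n)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
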