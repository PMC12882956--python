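import numpy as np
import pytest

import gcim


@pytest.fixture(scope="session")
def small_dataset():
    """A modest quantitative dataset with real signal, shared across tests."""
    cfg = gcim.EffectCovConfig(var_add=0.4, var_add_c=0.5, n_causal=50)
    G, phen, eff = gcim.simulate_dataset(cfg, n=1500, m=200, seed=11)
    return cfg, G, phen, eff


@pytest.fixture(scope="session")
def fixed_fixture_20():
    """Tiny deterministic fixture for exact-oracle comparisons."""
    rng = np.random.default_rng(7)
    n, m = 20, 5
    counts = rng.binomial(2, 0.4, size=(n, m)).astype(float)
    G = gcim.GenotypeMatrix(
        counts=counts,
        snp_ids=np.array([f"s{j}" for j in range(m)]),
        allele_freqs=np.full(m, 0.4),
        individual_ids=np.array([f"i{k}" for k in range(n)]),
    )
    y = rng.standard_normal(n)
    c = rng.standard_normal(n)
    return G, y, c
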