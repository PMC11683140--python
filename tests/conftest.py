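import numpy as np
import pandas as pd
import pytest

from cassgs import markers as mk
from cassgs import simulate as sim


@pytest.fixture
def toy():
    """The hard-coded 8-clone x 6-marker fixture with its trial table."""
    return sim.toy_fixture()


@pytest.fixture(scope="session")
def geno80():
    """80 clones x 300 markers, HWE-simulated, no missing calls."""
    cfg = sim.SimulationConfig(n_clones=80, n_markers=300,
                               maf_range=(0.1, 0.5), seed=11)
    return sim.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def matrices80(geno80):
    """(G, D, K) built once for the 80-clone panel."""
    return (mk.build_additive_grm(geno80),
            mk.build_dominance_grm(geno80),
            mk.build_gaussian_kernel(geno80, 1.0))


def sample_polygenic(G_values, s2a, s2e, seed):
    """y ~ N(0, s2a*G + s2e*I) as a clone-indexed Series helper."""
    n = G_values.shape[0]
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(G_values + 1e-8 * np.eye(n))
    return np.sqrt(s2a) * (L @ rng.standard_normal(n)) \
        + np.sqrt(s2e) * rng.standard_normal(n)


@pytest.fixture(scope="session")
def y80(geno80, matrices80):
    """Additive-signal response over the 80-clone panel (h2 = 0.5)."""
    G = matrices80[0]
    y = sample_polygenic(G.values, 1.0, 1.0, seed=17)
    return pd.Series(y, index=pd.Index(geno80.clone_ids, name="clone"))
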