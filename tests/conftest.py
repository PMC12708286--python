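import numpy as np
import pandas as pd
import pytest

from mitodx.simulate import SimConfig, simulate_cohorts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def single_cohort():
    """One clean cohort with planted DE genes and modules (no batch effects)."""
    cfg = SimConfig(
        n_cohorts=1, n_control=20, n_treat=20, n_genes=500,
        module_sizes=(100, 80), n_de_genes=40, delta=2.0,
        batch_shift_sd=0.0, batch_scale_range=(1.0, 1.0), noise_sd=1.0,
        seed=42,
    )
    matrices, pheno, truth = simulate_cohorts(cfg)
    return matrices[0], pheno, truth, cfg


@pytest.fixture
def separable_cohorts(rng):
    """Strongly separable train + 3 validation cohorts for model benchmarks."""
    p = 28
    cols = [f"g{i:02d}" for i in range(p)]

    def make(n0, n1, seed):
        r = np.random.default_rng(seed)
        y = np.array([0] * n0 + [1] * n1)
        X = r.normal(size=(n0 + n1, p))
        X[:, :8] += 1.5 * y[:, None]
        return pd.DataFrame(X, columns=cols), y

    Xtr, ytr = make(45, 75, 10)
    validations = {f"v{i}": make(20, 30, 20 + i) for i in range(3)}
    return Xtr, ytr, validations
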