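import numpy as np
import pytest

from wmnet import behavior, synthetic


@pytest.fixture(scope="session")
def default_schedule():
    return behavior.build_schedule(seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate-noise dataset with batch effects and planted behavior/FA."""
    cfg = synthetic.SyntheticConfig(
        n_subjects=150,
        grid_dims=(12, 12, 12),
        n_components_true=3,
        noise_sd=0.4,
        seed=7,
    )
    return cfg, synthetic.generate_dataset(cfg)


def sparse_mixture(k, m, n, noise_sd, seed, sparsity=0.08):
    """Direct sparse-Laplace mixture X = A S + noise with z-scaled rows/cols."""
    rng = np.random.default_rng(seed)
    S = np.zeros((k, n))
    per = max(1, int(round(sparsity * n)))
    for c in range(k):
        sup = rng.choice(n, size=per, replace=False)
        S[c, sup] = rng.laplace(0, 1, per)
    S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
    A = rng.standard_normal((m, k))
    A = (A - A.mean(0)) / A.std(0)
    X = A @ S
    if noise_sd > 0:
        X = X + rng.normal(0, noise_sd, (m, n))
    return X, S, A
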