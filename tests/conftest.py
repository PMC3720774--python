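import numpy as np
import pytest

import bacon
from bacon.vb_engine import init_posterior, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_instance(seed: int, *, K: int = 2, G: int = 6, T: int = 5,
                   n_series: int = 2, sweeps: int = 0):
    """Standardized small data set plus an initialized (optionally pre-swept)
    posterior state, for update-level tests."""
    rng = np.random.default_rng(seed)
    K_true = min(K, G)
    spec = bacon.SimSpec(K=K_true, G=G, T=T, n_series=n_series,
                         state_noise_sd=0.3, seed=seed)
    data, params, gold = bacon.simulate(spec)
    sdata, _ = standardize(data)
    cfg = bacon.ModelConfig(K=K, seed=seed + 1)
    state = init_posterior(sdata, cfg)
    for _ in range(sweeps):
        bacon.update_states(state, sdata)
        bacon.update_dynamics(state, sdata)
        bacon.update_memberships(state, sdata)
        bacon.update_precisions(state, sdata)
        bacon.update_hyperparameters(state)
    return sdata, state, params, gold


def concordance_auroc(y_true, y_score) -> float:
    """O(n^2) pairwise-comparison AUROC oracle with half-credit for ties."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    pos = y_score[y_true == 1]
    neg = y_score[y_true == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
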