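import itertools

import numpy as np
import pytest

from mosaic import hmm

# compositions with every state (canonical and partner) well separated in
# (T+A, T+C, T+G) space -- the regime in which replicate training is
# identifiable
RECOVERY_COMPOSITIONS = (
    (0.55, 0.10, 0.05, 0.30),
    (0.10, 0.45, 0.25, 0.20),
    (0.25, 0.35, 0.05, 0.35),
    (0.15, 0.20, 0.10, 0.55),
)


def random_model(K: int, rng: np.random.Generator) -> hmm.MosaicModel:
    """Arbitrary valid (not necessarily symmetric) model for oracle tests."""
    pair = np.arange(K) ^ 1
    return hmm.MosaicModel(
        pi=rng.dirichlet(np.ones(K)),
        A=rng.dirichlet(np.ones(K), size=K),
        E=rng.dirichlet(np.ones(4), size=(K, 4)),
        e0=rng.dirichlet(np.ones(4), size=K),
        pair=pair,
    )


def random_symmetric_model(n_pairs: int, rng: np.random.Generator) -> hmm.MosaicModel:
    return hmm.reimpose_symmetry(random_model(2 * n_pairs, rng))


def brute_force_posterior(model: hmm.MosaicModel, seq: str):
    """Exhaustive path enumeration: (log-likelihood, posterior, best path)."""
    obs = hmm.encode(seq)
    K, L = model.K, len(obs)
    total = 0.0
    post = np.zeros((L, K))
    best_p, best_path = -1.0, None
    for path in itertools.product(range(K), repeat=L):
        p = model.pi[path[0]] * model.e0[path[0], obs[0]]
        for t in range(1, L):
            p *= model.A[path[t - 1], path[t]] * model.E[path[t], obs[t - 1], obs[t]]
        total += p
        for t, s in enumerate(path):
            post[t, s] += p
        if p > best_p:
            best_p, best_path = p, path
    return np.log(total), post / total, np.array(best_path)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
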