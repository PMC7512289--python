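import numpy as np
import pytest

from vcgpdm import SyntheticSpec, VCGPDM, make_dataset
from vcgpdm.synthetic import valid_seeds


@pytest.fixture(scope="session")
def small_data():
    """A small non-degenerate coupled two-part dataset (3 trials, T=60)."""
    seed = valid_seeds(3, 1, T=60)[0]
    data, truth = make_dataset(SyntheticSpec(T=60, seed=seed, n_trials=3))
    return data, truth, seed


@pytest.fixture(scope="session")
def fitted(small_data):
    """A modestly trained model shared across tests that only need *a*
    trained model, not a well-trained one."""
    data, _, seed = small_data
    model = VCGPDM(data, latent_dims=2, order=2, n_dyn_ips=5, n_kin_ips=6,
                   seed=seed)
    results = model.fit(joint_maxiter=150, block_maxiter=50, max_cycles=1)
    return model, results


def finite_difference(f, x0, eps=1e-6):
    """Central finite-difference gradient of a scalar function of an array."""
    x0 = np.asarray(x0, dtype=float)
    g = np.zeros_like(x0)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x0.copy()
        xp[i] += eps
        xm = x0.copy()
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
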