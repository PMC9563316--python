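import numpy as np
import pytest

import metstab as ms

STUDY_SHAPE = dict(n_genotypes=11, n_environments=5, rank=2, n_rep=3)


@pytest.fixture(scope="session")
def exact_truth():
    """Noise-free rank-2 truth at the study shape (11 x 5 x 3)."""
    return ms.random_truth(seed=11, effect_scales={"block_sd": 0.0, "error_sd": 0.0},
                           **{k: v for k, v in STUDY_SHAPE.items() if k != "n_rep"},
                           n_rep=STUDY_SHAPE["n_rep"])


@pytest.fixture(scope="session")
def exact_data(exact_truth):
    return ms.simulate_trait(exact_truth, trait="exact")


@pytest.fixture(scope="session")
def noisy_truth():
    return ms.random_truth(seed=5, **STUDY_SHAPE)


@pytest.fixture(scope="session")
def noisy_data(noisy_truth):
    return ms.simulate_trait(noisy_truth, trait="noisy")


@pytest.fixture(scope="session")
def noisy_ammi(noisy_data):
    return ms.AMMI.from_dataset(noisy_data, "noisy").fit()


@pytest.fixture(scope="session")
def panel():
    """Small noisy multi-trait panel for cross-module tests."""
    return ms.simulate_multitrait(6, seed=19)


def brute_force_double_center(y: np.ndarray) -> np.ndarray:
    """Independent double-centring by explicit loops (oracle)."""
    G, E = y.shape
    z = np.empty_like(y, dtype=float)
    grand = y.mean()
    for i in range(G):
        for j in range(E):
            z[i, j] = y[i, j] - y[i, :].mean() - y[:, j].mean() + grand
    return z
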