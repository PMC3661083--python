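import numpy as np
import pytest

from eipr import VarModelSpec, simulate_var, winterhalder_model

#: Directed pairs (target, source) with imposed dependencies in the
#: 4-channel benchmark, 0-indexed: x2->x1, x4->x2, x1->x3, x2->x3.
CAUSAL_PAIRS = [(0, 1), (1, 3), (2, 0), (2, 1)]
NONCAUSAL_PAIRS = [
    (k, l) for k in range(4) for l in range(4)
    if k != l and (k, l) not in CAUSAL_PAIRS
]


@pytest.fixture(scope="session")
def benchmark():
    return winterhalder_model()


@pytest.fixture(scope="session")
def benchmark_recording(benchmark):
    """One 100 s benchmark realization at 128 Hz (12800 samples)."""
    return simulate_var(benchmark, 12800, seed=1)


@pytest.fixture(scope="session")
def ar1_spec():
    return VarModelSpec(coeffs=np.array([[[0.8]]]), noise_cov=np.array([[1.0]]))


def random_stable_sparse_spec(rng: np.random.Generator, K: int = 3, p: int = 2):
    """Random sparse VAR spec, rescaled until the companion radius is < 0.95."""
    while True:
        A = rng.standard_normal((p, K, K)) * 0.4
        A[rng.random((p, K, K)) < 0.5] = 0.0
        # keep every channel's intrinsic dynamics alive
        for k in range(K):
            if np.all(A[:, k, k] == 0):
                A[0, k, k] = 0.3
        spec = VarModelSpec(coeffs=A, noise_cov=np.eye(K))
        rho = spec.spectral_radius()
        if rho < 0.95:
            return spec
        A *= 0.8 / max(rho, 1e-6)
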