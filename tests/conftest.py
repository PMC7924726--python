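import numpy as np
import pytest

from kernelgrn.data_io import FeatureMatrix, RegulationMatrix
from kernelgrn.kernels import KernelMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_linear_kernel():
    """1-D points (-2, -1, +1, +2) under the linear kernel; the separable
    toy whose SVM solution is known in closed form (f(x) = x)."""
    x = np.array([-2.0, -1.0, 1.0, 2.0])
    K = np.outer(x, x)
    y = np.array([-1.0, -1.0, 1.0, 1.0])
    return x, K, y


def random_psd_kernel(rng, n, ids=None):
    A = rng.standard_normal((n, max(2, n // 2)))
    K = A @ A.T + 1e-6 * np.eye(n)
    return KernelMatrix(ids or [f"g{i}" for i in range(n)], K, kind="linear")


def small_problem(seed=0, n_genes=30, n_tfs=3):
    """A tiny aligned (kernel, regulations) pair with planted structure."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    tfs = [f"TF{j}" for j in range(n_tfs)]
    base = rng.standard_normal((n_genes, 12))
    labels = -np.ones((n_genes, n_tfs), dtype=np.int8)
    for j in range(n_tfs):
        targets = rng.choice(n_genes, size=6, replace=False)
        base[targets] = rng.standard_normal(12) + 0.3 * rng.standard_normal((6, 12))
        labels[targets, j] = 1
    X = FeatureMatrix(genes, [f"s{i}" for i in range(12)], base)
    R = RegulationMatrix(genes, tfs, labels)
    return X, R
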