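"""Kernel construction and fusion.

Each genomic dataset is turned into a symmetric positive-semidefinite
gene x gene similarity matrix and the per-dataset kernels are fused by a
non-negative weighted sum K = sum_i mu_i k_i (uniform weights by default,
i.e. the plain kernel sum).  Vectorial data (expression, methylation) use
the Gaussian RBF kernel; graph data (PPI) use the diffusion kernel
K = exp(beta * H) with H = A - D, the negative graph Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_io import FeatureMatrix, GeneGraph, _check_unique

__all__ = [
    "KernelMatrix",
    "KernelWeights",
    "rbf_kernel",
    "diffusion_kernel",
    "linear_kernel",
    "normalize_kernel",
    "combine_kernels",
    "validate_psd",
]

_SYM_TOL = 1e-10


@dataclass
class KernelMatrix:
    """Symmetric PSD gene x gene similarity matrix with aligned identifiers."""

    gene_ids: list[str]
    values: np.ndarray
    kind: str = "combined"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kernel shape {self.values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(np.diag(self.values))):
            raise ValueError("kernel diagonal contains non-finite entries")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > _SYM_TOL * max(1.0, np.max(np.abs(self.values))):
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:.3g})")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def block(self, rows: Sequence[int], cols: Sequence[int]) -> np.ndarray:
        return self.values[np.ix_(rows, cols)]


@dataclass
class KernelWeights:
    """Non-negative fusion weights mu, one per candidate kernel."""

    mu: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.ndim != 1:
            raise ValueError("mu must be a vector")
        if np.any(self.mu < 0):
            raise ValueError("kernel weights must be non-negative")

    @classmethod
    def uniform(cls, m: int) -> "KernelWeights":
        return cls(np.ones(m))


def _median_gamma(X: np.ndarray, subsample: int, subsample_seed: int) -> float:
    """gamma = 1 / (2 m^2), m the median pairwise Euclidean distance.

    For large gene sets the median is taken over a deterministic seeded
    subsample so the default stays reproducible and cheap.
    """
    n = X.shape[0]
    if n > subsample:
        rng = np.random.default_rng(subsample_seed)
        X = X[np.sort(rng.choice(n, size=subsample, replace=False))]
    m = float(np.median(pdist(X))) if X.shape[0] > 1 else 0.0
    if m <= 0:
        raise ValueError(
            "median pairwise distance is zero (degenerate input); "
            "pass an explicit gamma"
        )
    return 1.0 / (2.0 * m * m)


def rbf_kernel(
    X: FeatureMatrix,
    gamma: float | str = "median",
    subsample: int = 1000,
    subsample_seed: int = 0,
) -> KernelMatrix:
    """Gaussian RBF kernel over gene rows: K_ij = exp(-gamma ||x_i - x_j||^2)."""
    if X.n_samples < 1:
        raise ValueError("feature matrix needs at least one sample")
    if gamma == "median":
        gamma = _median_gamma(X.values, subsample, subsample_seed)
    gamma = float(gamma)
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    d2 = squareform(pdist(X.values, metric="sqeuclidean"))
    K = np.exp(-gamma * d2)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(list(X.gene_ids), K, kind="rbf", params={"gamma": gamma})


def diffusion_kernel(G: GeneGraph, beta: float = 1.0, order: Sequence[str] | None = None) -> KernelMatrix:
    """Graph diffusion kernel K = exp(beta * H), H = A - D.

    A is the (weighted) adjacency matrix and D the diagonal degree matrix,
    so H is the negative graph Laplacian.  The matrix exponential is
    computed by symmetric eigendecomposition, which keeps K exactly
    symmetric PSD.  Because H has zero row sums, every row of K sums to 1.
    """
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    gene_ids = list(order) if order is not None else sorted(G.gene_ids)
    A = G.adjacency(gene_ids)
    H = A - np.diag(A.sum(axis=1))
    w, V = np.linalg.eigh(H)
    K = (V * np.exp(beta * w)) @ V.T
    K = 0.5 * (K + K.T)
    return KernelMatrix(gene_ids, K, kind="diffusion", params={"beta": float(beta)})


def linear_kernel(X: FeatureMatrix) -> KernelMatrix:
    """Plain inner-product kernel K = X X^T over gene rows."""
    return KernelMatrix(list(X.gene_ids), X.values @ X.values.T, kind="linear")


def normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Cosine (unit-diagonal) normalization: K'_ij = K_ij / sqrt(K_ii K_jj)."""
    d = np.diag(K.values)
    if np.any(d <= 0):
        bad = K.gene_ids[int(np.argmax(d <= 0))]
        raise ValueError(f"non-positive kernel diagonal for gene {bad!r}")
    s = 1.0 / np.sqrt(d)
    Kn = K.values * np.outer(s, s)
    np.fill_diagonal(Kn, 1.0)
    return KernelMatrix(
        list(K.gene_ids), Kn, kind=K.kind, params={**K.params, "normalized": True}
    )


def combine_kernels(ks: Sequence[KernelMatrix], w: KernelWeights | None = None) -> KernelMatrix:
    """Fuse kernels by the weighted sum K = sum_i mu_i k_i (uniform default)."""
    if not ks:
        raise ValueError("need at least one kernel")
    if w is None:
        w = KernelWeights.uniform(len(ks))
    if len(w.mu) != len(ks):
        raise ValueError(f"{len(w.mu)} weights for {len(ks)} kernels")
    ref = ks[0].gene_ids
    for k in ks[1:]:
        if k.gene_ids != ref:
            raise ValueError("kernels have mismatched gene orders; align first")
    V = sum(mu * k.values for mu, k in zip(w.mu, ks))
    return KernelMatrix(
        list(ref),
        V,
        kind="combined",
        params={"mu": [float(m) for m in w.mu], "kinds": [k.kind for k in ks]},
    )


def validate_psd(K: KernelMatrix, tol: float = 1e-8) -> tuple[bool, float]:
    """Check numerical positive semidefiniteness.

    Returns (ok, lambda_min) with ok iff lambda_min >= -tol * max(1, lambda_max).
    """
    w = np.linalg.eigvalsh(K.values)
    lam_min, lam_max = float(w[0]), float(w[-1])
    return lam_min >= -tol * max(1.0, lam_max), lam_min
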