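"""1-norm soft-margin SVM on a precomputed (combined) kernel.

Each TF defines one binary classification problem: genes known to be
regulated by the TF are +1, everything else -1.  The classifier is the
standard 1-norm soft-margin SVM solved in its dual form

    max_alpha  sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K_ij
    s.t.       0 <= alpha_i <= C_i,   sum_i alpha_i y_i = 0,

trained directly on the fused kernel matrix.  The dual is solved by the
SMO solver behind scikit-learn's SVC (any solver meeting the KKT
residual contract below is acceptable); :func:`kkt_residuals` verifies
the contract post hoc for every trained model.

Because known targets are rare at genome scale, the per-class penalty
defaults to C_+ = C * (n_- / n_+), C_- = C, preventing the trivial
all-negative solution; ``class_weighting=False`` restores the plain
formulation.

An optional alternating p-norm weight learner (:func:`learn_weights`)
tunes the fusion weights mu; by default fusion is the unweighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .kernels import KernelMatrix, KernelWeights

__all__ = ["SvmParams", "TrainedTFModel", "train", "decision_scores", "kkt_residuals", "learn_weights"]


@dataclass
class SvmParams:
    """Soft-margin penalty C, solver tolerance epsilon, and the kernel-weight
    norm p used only by the optional MKL weight learner."""

    C: float = 1.0
    epsilon: float = 1e-5
    norm: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.norm < 1:
            raise ValueError(f"norm must be >= 1, got {self.norm}")


@dataclass
class TrainedTFModel:
    """Dual solution for one TF: coefficients alpha over the training genes,
    their labels, the bias, and the per-point box bound C_i."""

    support_ids: list[str]
    alpha: np.ndarray
    labels: np.ndarray
    bias: float
    box: np.ndarray
    mu: KernelWeights | None = None
    params: SvmParams = field(default_factory=SvmParams)

    @property
    def coef(self) -> np.ndarray:
        """alpha_i * y_i, the expansion coefficients of the decision function."""
        return self.alpha * self.labels


def _as_matrix(K) -> np.ndarray:
    return K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def train(
    K_train,
    y: Sequence[float],
    p: SvmParams | None = None,
    ids: Sequence[str] | None = None,
    class_weighting: bool = True,
) -> TrainedTFModel:
    """Fit the dual SVM on a precomputed training kernel block.

    ``K_train`` is the kernel restricted to the training genes (a
    KernelMatrix or square ndarray); ``y`` the +-1 labels.
    """
    p = p or SvmParams()
    K = _as_matrix(K_train)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K.shape != (n, n):
        raise ValueError(f"kernel block {K.shape} does not match {n} labels")
    classes = set(np.unique(y))
    if classes != {-1.0, 1.0}:
        raise ValueError(f"degenerate labels: need both +1 and -1, got {sorted(classes)}")
    if ids is None:
        if isinstance(K_train, KernelMatrix):
            ids = K_train.gene_ids
        else:
            ids = [str(i) for i in range(n)]
    n_pos = int((y == 1).sum())
    n_neg = n - n_pos
    class_weight = {1: n_neg / n_pos, -1: 1.0} if class_weighting else None
    # libsvm's stopping rule bounds the final KKT violation by tol; run a
    # decade below epsilon so the post-hoc residual contract holds.
    clf = SVC(kernel="precomputed", C=p.C, tol=p.epsilon / 10.0, class_weight=class_weight)
    clf.fit(K, y)
    alpha = np.zeros(n)
    alpha[clf.support_] = np.abs(clf.dual_coef_[0])
    box = np.full(n, p.C)
    if class_weight is not None:
        box[y == 1] = p.C * class_weight[1]
    return TrainedTFModel(
        support_ids=list(ids),
        alpha=alpha,
        labels=y,
        bias=float(clf.intercept_[0]),
        box=box,
        params=p,
    )


def decision_scores(m: TrainedTFModel, K_cross) -> np.ndarray:
    """Decision values f(g) = sum_i alpha_i y_i K(g, i) + bias.

    ``K_cross`` has query genes as rows and the model's training genes as
    columns (column order must match ``m.support_ids``).  Higher scores
    mean "more likely regulated".
    """
    K = np.asarray(K_cross, dtype=float)
    if K.ndim == 1:
        K = K[None, :]
    if K.shape[1] != len(m.alpha):
        raise ValueError(
            f"K_cross has {K.shape[1]} columns but the model has {len(m.alpha)} training points"
        )
    return K @ m.coef + m.bias


def kkt_residuals(m: TrainedTFModel, K_train, atol: float = 1e-8) -> dict[str, float]:
    """Post-hoc optimality residuals of the dual solution.

    Returns the violations of the box constraints, the equality constraint
    sum_i alpha_i y_i = 0, and the stationarity/complementary-slackness
    conditions expressed through margins y_i f(x_i):

      alpha_i = 0          ->  y_i f_i >= 1
      0 < alpha_i < C_i    ->  y_i f_i  = 1
      alpha_i = C_i        ->  y_i f_i <= 1
    """
    K = _as_matrix(K_train)
    f = K @ m.coef + m.bias
    margins = m.labels * f
    at_zero = m.alpha <= atol
    at_box = m.alpha >= m.box - atol
    free = ~(at_zero | at_box)
    res_lower = float(np.max(np.maximum(1.0 - margins[at_zero], 0.0), initial=0.0))
    res_upper = float(np.max(np.maximum(margins[at_box] - 1.0, 0.0), initial=0.0))
    res_free = float(np.max(np.abs(margins[free] - 1.0), initial=0.0))
    return {
        "box": float(max(np.max(-m.alpha, initial=0.0), np.max(m.alpha - m.box, initial=0.0))),
        "equality": float(abs(np.dot(m.alpha, m.labels))),
        "stationarity": max(res_lower, res_upper, res_free),
    }


def dual_objective(alpha: np.ndarray, y: np.ndarray, K: np.ndarray) -> float:
    """Dual objective sum alpha - 1/2 (alpha y)^T K (alpha y)."""
    v = alpha * y
    return float(alpha.sum() - 0.5 * v @ K @ v)


def learn_weights(
    ks: Sequence[KernelMatrix],
    y: Sequence[float],
    p: SvmParams | None = None,
    max_iter: int = 50,
    class_weighting: bool = True,
) -> KernelWeights:
    """Alternating p-norm MKL: learn non-negative fusion weights mu.

    Iterates (i) train the SVM on K = sum_m mu_m k_m, (ii) update
    mu_m proportional to (||w_m||^2)^{1/(p+1)} where
    ||w_m||^2 = mu_m^2 (alpha y)^T k_m (alpha y), normalized to
    ||mu||_p = 1, until the relative change of the dual objective drops
    below epsilon.  Returns the best iterate; ``converged`` is False if
    max_iter was exhausted first.
    """
    p = p or SvmParams()
    if len(ks) < 2:
        raise ValueError("weight learning needs at least 2 kernels")
    y = np.asarray(y, dtype=float)
    mats = [_as_matrix(k) for k in ks]
    m = len(mats)
    mu = np.full(m, m ** (-1.0 / p.norm))  # uniform with ||mu||_p = 1
    prev_obj = None
    best = (np.inf, mu, False)
    converged = False
    for _ in range(max_iter):
        K = sum(w * km for w, km in zip(mu, mats))
        model = train(K, y, p, class_weighting=class_weighting)
        obj = dual_objective(model.alpha, y, K)
        if obj < best[0]:
            best = (obj, mu.copy(), converged)
        if prev_obj is not None and abs(obj - prev_obj) <= p.epsilon * max(1.0, abs(prev_obj)):
            converged = True
            break
        prev_obj = obj
        v = model.coef
        w2 = np.array([max(w * w * (v @ km @ v), 0.0) for w, km in zip(mu, mats)])
        if w2.sum() <= 0:
            break
        mu = w2 ** (1.0 / (p.norm + 1.0))
        mu /= np.linalg.norm(mu, ord=p.norm)
    return KernelWeights(best[1] if not converged else mu, converged=converged)
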