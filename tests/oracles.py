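"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: the SVM dual is
solved by a generic constrained optimizer, AUC by explicit pairwise
concordance counting, and AUPR by an explicit threshold sweep.
"""

import numpy as np
from scipy.optimize import minimize


def solve_svm_dual_qp(K, y, C, box=None):
    """Generic QP solution of the soft-margin SVM dual via SLSQP.

    max sum a - 1/2 (a*y)' K (a*y)  s.t.  0 <= a_i <= box_i, sum a_i y_i = 0.
    Returns (alpha, dual objective value).
    """
    K = np.asarray(K, float)
    y = np.asarray(y, float)
    n = len(y)
    box = np.full(n, C) if box is None else np.asarray(box, float)
    Q = (y[:, None] * K * y[None, :])

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def grad(a):
        return -(np.ones(n) - Q @ a)

    res = minimize(
        neg_obj,
        x0=np.zeros(n),
        jac=grad,
        bounds=[(0.0, b) for b in box],
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return res.x, -res.fun


def pairwise_auc(scores, labels):
    """Concordance probability by enumeration of all (pos, neg) pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def sweep_aupr(scores, labels):
    """Rectangular PR-curve area by explicit sweep over descending unique
    score thresholds."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    n_pos = int((labels == 1).sum())
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == -1)))
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area
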