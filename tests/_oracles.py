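"""Independent reference implementations used only to check the package.

The FISTA proximal-gradient solver below shares no code with the
coordinate-descent implementation; it minimizes the same objective

    (1/2n)||y - b0 - X beta||^2 + lam * sum_j w_j [a|b_j| + (1-a)/2 b_j^2]

by accelerated proximal steps on centered data.
"""

import numpy as np


def soft_threshold(v, t):
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def prox_elastic_net(v, step, lam, alpha, w):
    """Prox of step * lam * w * (alpha |b| + (1-alpha)/2 b^2), elementwise."""
    return soft_threshold(v, step * lam * alpha * w) / (
        1.0 + step * lam * (1.0 - alpha) * w)


def fista_elastic_net(X, y, penalty, alpha, lam, n_iter=200_000, tol=1e-14):
    """Reference solution: returns (intercept, beta)."""
    n = len(y)
    xbar, ybar = X.mean(axis=0), y.mean()
    Xc, yc = X - xbar, y - ybar
    L = np.linalg.norm(Xc, 2) ** 2 / n
    step = 1.0 / L
    beta = np.zeros(X.shape[1])
    z = beta.copy()
    t = 1.0
    for _ in range(n_iter):
        grad = Xc.T @ (Xc @ z - yc) / n
        new = prox_elastic_net(z - step * grad, step, lam, alpha, penalty)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = new + (t - 1.0) / t_new * (new - beta)
        delta = np.abs(new - beta).max()
        beta, t = new, t_new
        if delta < tol:
            break
    intercept = ybar - xbar @ beta
    return intercept, beta


def auc_brute_force(labels, scores):
    """AUC by explicit enumeration of all positive-negative pairs."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
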