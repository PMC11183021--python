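"""Independent oracles used to cross-check the package implementations.

Each function here is deliberately written from first principles (brute
force, enumeration, or a textbook formula) and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def newton_logistic(X: np.ndarray, y: np.ndarray, tol=1e-12, maxiter=200):
    """Plain Newton-Raphson MLE for logistic regression (intercept first)."""
    X = np.column_stack([np.ones(len(X)), X])
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def brute_force_dilation(tumor, liver, spacing, radius_mm):
    """Peritumoral mask by explicit pairwise physical distances."""
    tumor = np.asarray(tumor, bool)
    liver = np.asarray(liver, bool)
    spacing = np.asarray(spacing, float)
    tum_idx = np.argwhere(tumor).astype(float) * spacing
    out = np.zeros_like(tumor)
    for idx in np.argwhere(np.ones_like(tumor)):
        if tumor[tuple(idx)] or not liver[tuple(idx)]:
            continue
        pos = idx.astype(float) * spacing
        d = np.sqrt(((tum_idx - pos) ** 2).sum(axis=1)).min()
        if d <= radius_mm:
            out[tuple(idx)] = True
    return out


def ecdf_survival(times, grid):
    """Empirical survival function S(t) = P(T > t) evaluated on a grid."""
    times = np.asarray(times, float)
    return np.array([(times > t).mean() for t in grid])


def auc_by_pair_counting(scores, labels):
    """AUC as the fraction of concordant (pos, neg) pairs, half for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
        pos[:, None] == neg[None, :]
    ).sum()
    return wins / (pos.size * neg.size)


def jackknife_delong_variance(scores_a, scores_b, labels, auc_fn):
    """Leave-one-out jackknife variance of the paired AUC difference."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, bool)
    n = labels.size
    deltas = []
    for i in range(n):
        keep = np.arange(n) != i
        deltas.append(
            auc_fn(scores_a[keep], labels[keep]) - auc_fn(scores_b[keep], labels[keep])
        )
    deltas = np.asarray(deltas)
    return (n - 1) / n * ((deltas - deltas.mean()) ** 2).sum()


def logrank_oe_oracle(times1, times2):
    """Two-group log-rank chi-square by direct O-E / V bookkeeping.

    Assumes no censoring and untied event times across groups.
    """
    times1 = np.asarray(times1, float)
    times2 = np.asarray(times2, float)
    events = np.sort(np.concatenate([times1, times2]))
    o_minus_e = 0.0
    var = 0.0
    for t in events:
        n1 = (times1 >= t).sum()
        n2 = (times2 >= t).sum()
        n = n1 + n2
        d = 1  # one event at each distinct time
        e1 = d * n1 / n
        o1 = 1 if t in times1 else 0
        o_minus_e += o1 - e1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
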