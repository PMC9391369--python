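"""Low-level numerical kernels: L1-penalized logistic regression and AUROC.

The whole pipeline is built out of very many (10^5-10^6) penalized logistic
fits on tiny design matrices (n <= ~100 patients, p <= ~6 features: one marker
plus scheme covariates). The fits are therefore implemented as a
numba-compiled coordinate-descent solver rather than through a generic
estimator object, keeping a single fit in the microsecond range.

Objective (matching scikit-learn's parameterization so the two can be compared
directly):

    min_{w, b}  C * sum_i log(1 + exp(-t_i (x_i . w + b))) + ||w||_1

with t_i in {-1, +1} and an unpenalized intercept b. Internally we minimize
the equivalent  sum_i logloss_i + lam * ||w||_1  with lam = 1/C.

The solver is iteratively reweighted least squares with an inner penalized
weighted coordinate descent (the glmnet scheme): each outer step forms the
quadratic expansion of the log-likelihood at the current estimate (weights
mu(1-mu), floored for stability) and the inner loop solves the resulting
weighted lasso by soft-threshold coordinate updates. Converges to the optimum
of the convex objective; cross-checked against scikit-learn in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["fit_l1_logistic", "l1_logistic_objective", "auroc"]

_MAX_SWEEPS = 200


@njit(cache=False)
def _cd_l1_logistic(X, y, lam, tol, max_outer):
    """IRLS + penalized weighted coordinate descent for L1 logistic regression.

    X : (n, p) float64 design, no intercept column
    y : (n,) float64 labels in {0, 1}
    lam : L1 penalty on the non-intercept coefficients
    Returns (w, b).
    """
    n, p = X.shape
    w = np.zeros(p)
    b = 0.0
    eta = np.zeros(n)  # X @ w + b
    W = np.empty(n)
    u = np.empty(n)
    w_old = np.empty(p)

    for _ in range(max_outer):
        # quadratic expansion at the current estimate
        for i in range(n):
            mu = 1.0 / (1.0 + np.exp(-eta[i]))
            wi = mu * (1.0 - mu)
            if wi < 1e-6:
                wi = 1e-6
            W[i] = wi
            u[i] = eta[i] + (y[i] - mu) / wi  # working response

        for j in range(p):
            w_old[j] = w[j]
        b_old = b

        # inner CD on the weighted lasso
        for _inner in range(1000):
            max_step = 0.0
            # intercept (unpenalized)
            num = 0.0
            den = 0.0
            for i in range(n):
                num += W[i] * (u[i] - eta[i])
                den += W[i]
            step = num / den
            b += step
            for i in range(n):
                eta[i] += step
            if np.abs(step) > max_step:
                max_step = np.abs(step)

            for j in range(p):
                aj = 0.0
                gj = 0.0
                for i in range(n):
                    aj += W[i] * X[i, j] * X[i, j]
                    gj += W[i] * X[i, j] * (u[i] - eta[i])
                if aj <= 0.0:
                    w[j] = 0.0
                    continue
                v = aj * w[j] + gj
                if v > lam:
                    w_new = (v - lam) / aj
                elif v < -lam:
                    w_new = (v + lam) / aj
                else:
                    w_new = 0.0
                d = w_new - w[j]
                if d != 0.0:
                    w[j] = w_new
                    for i in range(n):
                        eta[i] += X[i, j] * d
                    if np.abs(d) > max_step:
                        max_step = np.abs(d)
            if max_step < 0.1 * tol:
                break

        # outer convergence: change of the coefficient vector
        delta = np.abs(b - b_old)
        for j in range(p):
            dj = np.abs(w[j] - w_old[j])
            if dj > delta:
                delta = dj
        if delta < tol:
            break
    return w, b


@njit(cache=False)
def _auroc_ranks(scores, y):
    """AUROC as the tie-corrected Mann-Whitney concordance (ties count 1/2)."""
    n = scores.shape[0]
    order = np.argsort(scores)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and scores[order[j + 1]] == scores[order[i]]:
            j += 1
        avg = 0.5 * (i + j) + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    n1 = 0
    s = 0.0
    for i in range(n):
        if y[i] == 1.0:
            n1 += 1
            s += ranks[i]
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    return (s - 0.5 * n1 * (n1 + 1)) / (n1 * n0)


def fit_l1_logistic(X, y, inverse_penalty, tol=1e-6, max_sweeps=_MAX_SWEEPS):
    """Fit an L1-regularized logistic regression with unpenalized intercept.

    Parameters
    ----------
    X : (n, p) array
        Design matrix (marker plus covariate columns; no intercept column).
    y : (n,) array
        Binary labels in {0, 1}. Both classes must be present.
    inverse_penalty : float
        Inverse regularization strength C > 0 (sklearn convention); smaller
        values penalize harder, C -> 0 shrinks all non-intercept
        coefficients to exactly zero.
    tol : float
        Convergence tolerance on the largest coefficient update in a sweep.

    Returns
    -------
    (beta, intercept) : ((p,) ndarray, float)
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("labels must be coded 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present to fit")
    if not inverse_penalty > 0:
        raise ValueError("inverse_penalty must be > 0")
    lam = 1.0 / float(inverse_penalty)
    w, b = _cd_l1_logistic(X, y, lam, float(tol), int(max_sweeps))
    return w, b


def l1_logistic_objective(X, y, beta, intercept, inverse_penalty):
    """Penalized objective C * sum log(1+exp(-t z)) + ||beta||_1 (sklearn scale)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    z = X @ np.asarray(beta, dtype=np.float64) + float(intercept)
    t = 2.0 * y - 1.0
    # numerically stable log(1 + exp(-t*z))
    loss = np.logaddexp(0.0, -t * z).sum()
    return float(inverse_penalty) * loss + np.abs(beta).sum()


def predict_proba(X, beta, intercept):
    """Class-1 probabilities under a fitted logistic model."""
    z = np.asarray(X, dtype=np.float64) @ np.asarray(beta, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-(z + float(intercept))))


def auroc(probabilities, labels):
    """Area under the ROC curve via the rank (Mann-Whitney) formula.

    Equals the probability that a random positive outranks a random negative,
    ties counted 1/2. Values below 0.5 are reported as-is: they indicate the
    scores rank the negative class higher (prediction of the opposite
    outcome), which is meaningful here and must not be clipped.
    """
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    yv = np.asarray(labels, dtype=np.float64).ravel()
    if p.shape != yv.shape:
        raise ValueError("probabilities and labels differ in length")
    out = _auroc_ranks(p, yv)
    if np.isnan(out):
        raise ValueError("AUROC undefined: only one class present")
    return float(out)
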