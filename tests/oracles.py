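"""Independent reference implementations used only to check the package.

These deliberately share no code with hybridpred.reml: the single-kernel
REML oracle works through the error-contrast spectral decomposition
(eigendecomposition of the projected kernel, 1-D search over the variance
ratio), and the ridge oracle solves the marker-effect normal equations
directly.
"""

import numpy as np
from scipy.optimize import minimize_scalar


def spectral_reml_single_kernel(y, K, X=None):
    """Profiled REML for y = X b + u + e, u ~ N(0, s2g K), via the spectral
    decomposition of the kernel projected onto error contrasts.

    Returns (restricted loglik, s2g, s2e) on the same likelihood scale as
    -0.5[(n-p) log 2pi + log|V| + log|X'V^-1X| + y'Py].
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if X is None:
        X = np.ones((n, 1))
    p = X.shape[1]
    # orthonormal basis of the orthogonal complement of col(X)
    Q, _ = np.linalg.qr(X, mode="complete")
    A = Q[:, p:]                      # n x (n-p), A'X = 0, A'A = I
    M = A.T @ K @ A
    xi, U = np.linalg.eigh(0.5 * (M + M.T))
    xi = np.maximum(xi, 0.0)
    eta = U.T @ (A.T @ y)
    m = n - p

    def neg_restricted_ll(log_delta):
        # delta = s2e / s2g; profile out s2g
        delta = np.exp(log_delta)
        denom = xi + delta
        s2g = float(np.sum(eta**2 / denom) / m)
        ll_contrast = -0.5 * (m * np.log(2 * np.pi) + m * np.log(s2g)
                              + np.sum(np.log(denom)) + m)
        return -ll_contrast

    res = minimize_scalar(neg_restricted_ll, bounds=(-25.0, 25.0),
                          method="bounded",
                          options={"xatol": 1e-12})
    delta = np.exp(res.x)
    s2g = float(np.sum(eta**2 / (xi + delta)) / m)
    s2e = float(delta * s2g)
    # convert contrast-likelihood to the |X'X|-free convention
    sign, logdetXtX = np.linalg.slogdet(X.T @ X)
    ll = -res.fun - 0.5 * logdetXtX
    return float(ll), s2g, s2e


def restricted_loglik_direct(y, X, Ks, sigma2s, sigma2_e):
    """Direct dense evaluation of the restricted log-likelihood."""
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    V = sigma2_e * np.eye(n)
    for s2, K in zip(sigma2s, Ks):
        V = V + s2 * K
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return float(-0.5 * ((n - p) * np.log(2 * np.pi) + ldV + ldX + y @ P @ y))


def ridge_marker_predictions(W_train, y_train, W_val, lam, mu):
    """rrBLUP: beta = (W'W + lam I)^-1 W'(y - mu); yhat = mu + W_val beta."""
    m = W_train.shape[1]
    beta = np.linalg.solve(W_train.T @ W_train + lam * np.eye(m),
                           W_train.T @ (y_train - mu))
    return mu + W_val @ beta
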