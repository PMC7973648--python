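"""Multi-kernel mixed model fitted by restricted maximum likelihood.

Model: ``y = X beta + sum_k u_k + e`` with ``u_k ~ N(0, sigma2_k K_k)`` and
``e ~ N(0, sigma2_e I)``; ``X`` defaults to an intercept. The restricted
log-likelihood is

    lR = -1/2 [ (n-p) log 2pi + log|V| + log|X' V^-1 X| + y' P y ]

with ``V = sum_k sigma2_k K_k + sigma2_e I`` and
``P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1``.

Optimization uses average-information (AI) updates with step halving and an
EM fallback whenever an AI proposal leaves the parameter space or fails to
improve the restricted likelihood; accepted steps are monotone in lR.
Variance components are pinned to a small floor (1e-8 * var(y)) instead of
exactly zero so V stays invertible.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .containers import MixedModelFit, RelationshipKernel

FLOOR_FACTOR = 1e-8
MAX_ITER = 200
TOL = 1e-6


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the log-likelihood trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _names(kernels: list[RelationshipKernel]) -> list[str]:
    names, seen = [], {}
    for k in kernels:
        base = f"{k.kind}:{k.layer}"
        seen[base] = seen.get(base, 0) + 1
        names.append(base if seen[base] == 1 else f"{base}#{seen[base]}")
    return names


def _reml_pieces(y, X, Ks, theta):
    """P matrix, P y, fixed effects and restricted loglik at theta.

    Only one O(n^3) factorization per call; traces against kernels are
    taken elementwise by the caller (tr(P K) = sum(P * K) for symmetric
    P, K).
    """
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for s2, K in zip(theta[:-1], Ks):
        V += s2 * K
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vi @ X
    XtViX = X.T @ ViX
    cx = linalg.cho_factor(XtViX, check_finite=False)
    logdetX = 2.0 * np.sum(np.log(np.diag(cx[0])))
    P = Vi - ViX @ linalg.cho_solve(cx, ViX.T, check_finite=False)
    Py = P @ y
    ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetX + float(y @ Py))
    beta = linalg.cho_solve(cx, ViX.T @ y, check_finite=False)
    return Vi, P, Py, beta, ll


def fit_reml(
    y: np.ndarray,
    kernels: list[RelationshipKernel],
    X: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> MixedModelFit:
    """Fit the multi-kernel model by AI-REML with EM fallback.

    All kernels must index the same individuals in the same order as ``y``.
    Raises :class:`ConvergenceError` if the likelihood has not stabilized
    within ``max_iter`` iterations.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    if not kernels:
        raise ValueError("at least one kernel required")
    ids = list(kernels[0].ids)
    for k in kernels:
        if list(k.ids) != ids or k.n != n:
            raise ValueError("kernels must share the ordering of y")
    if X is None:
        X = np.ones((n, 1))
    p = X.shape[1]
    names = _names(kernels)
    Ks = [k.matrix for k in kernels]
    K_all = Ks + [np.eye(n)]
    nk = len(Ks)

    vy = float(np.var(y))
    if vy < 1e-14:
        # degenerate: constant response
        floor = 1e-12
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return MixedModelFit(
            beta=beta, variance_components={nm: floor for nm in names},
            residual_variance=floor,
            blups={nm: np.zeros(n) for nm in names},
            loglik=np.nan, ids=ids, kernels=kernels, iterations=0,
            converged=True, floored=names + ["residual"], y=y, X=X,
        )
    floor = FLOOR_FACTOR * vy

    theta = np.full(nk + 1, vy / (nk + 1))
    _, P, Py, beta, ll = _reml_pieces(y, X, Ks, theta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # score and average information; tr(P K) computed elementwise
        KPy = [K @ Py for K in Ks] + [Py]
        trPK = [float(np.sum(P * K)) for K in Ks] + [float(np.trace(P))]
        score = np.array([
            -0.5 * (tr - float(Py @ kpy))
            for tr, kpy in zip(trPK, KPy)
        ])
        PKPy = [P @ v for v in KPy]
        AI = 0.5 * np.array([[float(KPy[i] @ PKPy[j]) for j in range(nk + 1)]
                             for i in range(nk + 1)])

        # components pinned at the floor with a negative score stay pinned
        pinned = (theta <= floor * (1 + 1e-9)) & (score < 0)
        free = np.flatnonzero(~pinned)
        if free.size == 0:
            converged = True
            break
        step = np.zeros(nk + 1)
        try:
            sub = AI[np.ix_(free, free)] + 1e-12 * np.eye(free.size)
            step[free] = np.linalg.solve(sub, score[free])
        except np.linalg.LinAlgError:
            step = None

        accepted = False
        if step is not None:
            frac = 1.0
            for _ in range(12):
                cand = np.maximum(theta + frac * step, floor)
                cand[pinned] = floor
                try:
                    _, P_c, Py_c, beta_c, ll_c = _reml_pieces(y, X, Ks, cand)
                except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
                    frac /= 2.0
                    continue
                if ll_c >= ll - 1e-10:
                    theta, P, Py, beta, ll = cand, P_c, Py_c, beta_c, ll_c
                    accepted = True
                    break
                frac /= 2.0
        if not accepted:
            # EM-REML update (Harville form), monotone in expectation
            cand = np.array([
                max(t + (t * t / n) * (float(Py @ kpy) - tr), floor)
                for t, kpy, tr in zip(theta, KPy, trPK)
            ])
            cand[pinned] = floor
            try:
                _, P_c, Py_c, beta_c, ll_c = _reml_pieces(y, X, Ks, cand)
            except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
                converged = abs(trace[-1] - trace[-2]) < tol if len(trace) > 1 else False
                break
            if ll_c < ll - 1e-8 and abs(ll_c - ll) > tol:
                # neither the AI step (after halving) nor EM improves the
                # restricted likelihood: a (possibly boundary) optimum at
                # the numerical precision limit
                converged = True
                break
            theta, P, Py, beta, ll = cand, P_c, Py_c, beta_c, ll_c
        trace.append(ll)
        # require two consecutive sub-tol changes: the extra Newton step
        # squares the parameter error once the likelihood has flattened
        if (abs(trace[-1] - trace[-2]) < tol
                and len(trace) > 2 and abs(trace[-2] - trace[-3]) < tol):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"AI-REML did not converge in {it} iterations "
            f"(last delta {abs(trace[-1] - trace[-2]):.3e})", trace)

    resid = y - X @ beta
    Vi, P, Py, beta, ll = _reml_pieces(y, X, Ks, theta)
    Vir = Vi @ (y - X @ beta)
    blups = {nm: theta[i] * (Ks[i] @ Vir) for i, nm in enumerate(names)}
    floored = [nm for nm, t in zip(names + ["residual"], theta) if t <= floor * (1 + 1e-9)]
    return MixedModelFit(
        beta=beta,
        variance_components={nm: float(theta[i]) for i, nm in enumerate(names)},
        residual_variance=float(theta[-1]),
        blups=blups, loglik=float(ll), ids=ids, kernels=kernels,
        iterations=it, converged=True, trace=trace, floored=floored,
        y=y, X=X,
    )


def predict_unobserved(
    fit: MixedModelFit,
    cross_blocks: list[np.ndarray],
    X_val: np.ndarray | None = None,
) -> np.ndarray:
    """BLUP predictions for unobserved individuals.

    ``cross_blocks[k]`` is ``K_k[val, train]`` for the k-th kernel of the
    fit, in the fit's kernel order. Implements

        y_val = X_val beta + sum_k sigma2_k K_k[val,train] V^-1 (y - X beta)
    """
    if fit.kernels is None or fit.y is None:
        raise ValueError("fit does not carry its training kernels")
    if len(cross_blocks) != len(fit.kernels):
        raise ValueError("one cross block per fitted kernel required")
    n = len(fit.ids)
    n_val = cross_blocks[0].shape[0]
    for cb in cross_blocks:
        if cb.shape != (n_val, n):
            raise ValueError("cross blocks must be (n_val, n_train) and aligned")
    s2 = list(fit.variance_components.values())
    V = fit.residual_variance * np.eye(n)
    for s, k in zip(s2, fit.kernels):
        V += s * k.matrix
    r = fit.y - fit.X @ fit.beta
    alpha = linalg.cho_solve(linalg.cho_factor(V, check_finite=False), r,
                             check_finite=False)
    if X_val is None:
        X_val = np.ones((n_val, fit.X.shape[1]))
    yhat = X_val @ fit.beta
    for s, cb in zip(s2, cross_blocks):
        yhat = yhat + s * (cb @ alpha)
    return yhat
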