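"""Multi-environment trial model and broad-sense heritability.

The trial model is ``Y = G + T + L + TxL + LxG + e`` with genotype fixed
(for BLUEs) or random (for variance components), trial, location and the
interactions random with identity covariance on their grouping factors.

Because every random term here is a grouping factor, the restricted
likelihood is evaluated through the low-rank identity
``(I + Z D Z')^-1 = I - Z (D^-1 + Z'Z)^-1 Z'`` on the (small) total number
of factor levels rather than the number of plots, and the residual
variance is profiled out; the remaining variance ratios are optimized on
the log scale with L-BFGS-B.

Broad-sense heritability uses the replicate-corrected form
``H2 = s2_G / (s2_G + s2_e / n0)`` with ``n0`` the number of plant
replicates per genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse


@dataclass
class TrialModelSpec:
    """Which columns of the long phenotype table play which role."""

    response: str = "value"
    genotype: str = "genotype"
    trial: str | None = "trial"
    location: str | None = "location"
    trial_x_location: bool = True
    location_x_genotype: bool = True
    all_random: bool = False


@dataclass
class TrialFit:
    """REML fit of the trial model."""

    blues: pd.Series | None           # per-genotype BLUE (None if all_random)
    blue_se: pd.Series | None
    variance_components: dict[str, float]
    residual_variance: float
    loglik: float
    converged: bool
    n_obs: int
    random_terms: list[str] = field(default_factory=list)


def _factor_Z(codes: np.ndarray, n_levels: int) -> sparse.csr_matrix:
    n = codes.shape[0]
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels))


def _interaction(c1, n1, c2, n2):
    return c1 * n2 + c2, n1 * n2


def fit_trial_model(data: pd.DataFrame, spec: TrialModelSpec | None = None,
                    genotype_levels=None) -> TrialFit:
    """Fit the multi-environment model by REML.

    With genotype fixed, returns per-genotype BLUEs and their standard
    errors; with ``all_random`` the genotype variance appears among the
    variance components instead. Random terms whose factor has fewer than
    two levels in the data are dropped. ``genotype_levels`` optionally
    fixes the output index: genotypes without any non-missing observation
    get a missing BLUE rather than being silently absent.
    """
    if spec is None:
        spec = TrialModelSpec()
    y = data[spec.response].to_numpy(dtype=float)
    keep = np.isfinite(y)
    data, y = data.loc[keep], y[keep]
    n = y.shape[0]
    if n == 0:
        raise ValueError("no non-missing observations")

    g_codes, g_levels = pd.factorize(data[spec.genotype].astype(str), sort=True)
    terms: dict[str, tuple[np.ndarray, int]] = {}
    t_codes = l_codes = None
    if spec.trial and spec.trial in data.columns:
        t_codes, t_lv = pd.factorize(data[spec.trial].astype(str), sort=True)
        if len(t_lv) > 1:
            terms["trial"] = (t_codes, len(t_lv))
    if spec.location and spec.location in data.columns:
        l_codes, l_lv = pd.factorize(data[spec.location].astype(str), sort=True)
        if len(l_lv) > 1:
            terms["location"] = (l_codes, len(l_lv))
    if spec.trial_x_location and "trial" in terms and "location" in terms:
        c, q = _interaction(terms["trial"][0], terms["trial"][1],
                            terms["location"][0], terms["location"][1])
        terms["trial:location"] = (c, q)
    if spec.location_x_genotype and "location" in terms:
        c, q = _interaction(terms["location"][0], terms["location"][1],
                            g_codes, len(g_levels))
        terms["location:genotype"] = (c, q)
    if spec.all_random:
        terms = {"genotype": (g_codes, len(g_levels)), **terms}
        X = np.ones((n, 1))
    else:
        X = _factor_Z(g_codes, len(g_levels)).toarray()
        counts = np.bincount(g_codes, minlength=len(g_levels))
        if np.any(counts == 0):
            missing = [g for g, c in zip(g_levels, counts) if c == 0]
            raise ValueError(f"genotypes without observations (aliased): {missing}")

    if not terms:
        # pure fixed-effects model: OLS genotype means
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        dof = max(n - X.shape[1], 1)
        s2e = float(np.sum((y - fitted) ** 2) / dof)
        se = np.sqrt(s2e / np.bincount(g_codes))
        blues = pd.Series(beta, index=list(g_levels))
        blue_se = pd.Series(se, index=list(g_levels))
        if genotype_levels is not None:
            blues = blues.reindex(list(genotype_levels))
            blue_se = blue_se.reindex(list(genotype_levels))
        return TrialFit(blues, blue_se, {}, s2e, np.nan, True, n, [])

    names = list(terms)
    Zs = [_factor_Z(c, q) for c, q in terms.values()]
    Z = sparse.hstack(Zs, format="csr")
    qk = [q for _, q in terms.values()]
    q_tot = sum(qk)
    block = np.repeat(np.arange(len(qk)), qk)

    ZtZ = (Z.T @ Z).toarray()
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    p = X.shape[1]

    def pieces(log_gamma):
        gamma = np.exp(log_gamma)
        d = gamma[block]
        B = ZtZ + np.diag(1.0 / d)
        cB, low = linalg.cho_factor(B, lower=True, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(cB))) + float(np.sum(np.log(d)))
        BiZtX = linalg.cho_solve((cB, low), ZtX, check_finite=False)
        BiZty = linalg.cho_solve((cB, low), Zty, check_finite=False)
        XtViX = XtX - ZtX.T @ BiZtX
        XtViy = Xty - ZtX.T @ BiZty
        ytViy = yty - float(Zty @ BiZty)
        cX = linalg.cho_factor(XtViX, check_finite=False)
        logdetX = 2.0 * np.sum(np.log(np.diag(cX[0])))
        beta = linalg.cho_solve(cX, XtViy, check_finite=False)
        ytPy = ytViy - float(beta @ XtViy)
        s2e = max(ytPy / (n - p), 1e-300)
        m2ll = ((n - p) * np.log(s2e) + logdetV + logdetX
                + (n - p) * (1.0 + np.log(2 * np.pi)))
        return m2ll, beta, s2e, cX, (cB, low)

    def objective(lg):
        try:
            return pieces(lg)[0]
        except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
            return 1e12

    x0 = np.full(len(qk), np.log(0.5))
    bounds = [(np.log(1e-10), np.log(1e8))] * len(qk)
    res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12})
    m2ll, beta, s2e, cX, _ = pieces(res.x)
    gamma = np.exp(res.x)
    comps = {nm: float(g * s2e) for nm, g in zip(names, gamma)}
    loglik = -0.5 * m2ll

    blues = blue_se = None
    if not spec.all_random:
        cov = linalg.cho_solve(cX, np.eye(p), check_finite=False) * s2e
        blues = pd.Series(beta, index=list(g_levels))
        blue_se = pd.Series(np.sqrt(np.diag(cov)), index=list(g_levels))
        if genotype_levels is not None:
            blues = blues.reindex(list(genotype_levels))
            blue_se = blue_se.reindex(list(genotype_levels))
    return TrialFit(blues, blue_se, comps, float(s2e), float(loglik),
                    bool(res.success), n, names)


def heritability(var_g: float, var_e: float, n0: int) -> float:
    """Replicate-corrected broad-sense heritability
    ``H2 = s2_G / (s2_G + s2_e / n0)``; NaN when both variances are zero."""
    if var_g < 0 or var_e < 0:
        raise ValueError("variance components must be nonnegative")
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if var_g == 0 and var_e == 0:
        return float("nan")
    return var_g / (var_g + var_e / n0)


def trait_heritability(data: pd.DataFrame, n0: int | None = None,
                       spec: TrialModelSpec | None = None) -> float:
    """Fit the all-random trial model and return the trait's H2.

    ``n0`` defaults to the median number of replicates per genotype.
    """
    if spec is None:
        spec = TrialModelSpec(all_random=True)
    else:
        spec = TrialModelSpec(**{**spec.__dict__, "all_random": True})
    fit = fit_trial_model(data, spec)
    if n0 is None:
        n0 = int(data.groupby(spec.genotype)["replicate"].nunique().median()) \
            if "replicate" in data.columns else 1
    return heritability(fit.variance_components.get("genotype", 0.0),
                        fit.residual_variance, n0)
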