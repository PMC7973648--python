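"""Relationship kernels: additive (VanRaden), dominance (Su), epistatic
(Hadamard square), and Gaussian kernels on Euclidean distances.

Genotype-based kernels use allele frequencies computed from the matrix they
are built from (the behaviour of the standard A.mat/D.mat implementations).
For quantitative layers (transcripts, metabolites) the "additive" kernel is
the mean-centred cross-product rescaled so its mean diagonal is 1, since an
allele-frequency denominator has no meaning there.

Squared Euclidean distances are divided by their off-diagonal mean before
exponentiation, so a single bandwidth grid is comparable across layers of
very different dimensionality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import DistanceMatrix, OmicsMatrix, RelationshipKernel

DEFAULT_BANDWIDTH_GRID = (0.01, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0)


def additive_kernel(om: OmicsMatrix, freq: np.ndarray | None = None) -> RelationshipKernel:
    """VanRaden additive relationship matrix.

    For genomic dosage matrices (0..2): ``W = M - 2p`` column-wise and
    ``K = W W' / (2 * sum p_j (1 - p_j))`` with ``p`` the column allele
    frequencies (computed from the matrix unless supplied). Monomorphic
    columns are dropped with a warning. For non-genotype layers the columns
    are mean-centred and the cross-product rescaled to mean diagonal 1.
    """
    M = om.values
    if om.layer == "genomic":
        p = M.mean(axis=0) / 2.0 if freq is None else np.asarray(freq, dtype=float)
        poly = (p > 0) & (p < 1)
        if not np.any(poly):
            raise ValueError("all SNPs monomorphic: additive kernel undefined")
        if not np.all(poly):
            warnings.warn(f"dropping {np.sum(~poly)} monomorphic SNPs")
            M, p = M[:, poly], p[poly]
        W = M - 2.0 * p
        denom = 2.0 * np.sum(p * (1.0 - p))
        K = (W @ W.T) / denom
    else:
        Z = M - M.mean(axis=0)
        if not np.any(Z.std(axis=0) > 0):
            raise ValueError("all features constant: kernel undefined")
        K = Z @ Z.T
        md = np.mean(np.diag(K))
        if md <= 0:
            raise ValueError("degenerate cross-product kernel")
        K = K / md
    return _stabilized(K, "additive", om.layer, om.individuals)


def dominance_kernel(om: OmicsMatrix, freq: np.ndarray | None = None) -> RelationshipKernel:
    """Dominance relationship matrix (Su et al. coding).

    Heterozygosity indicator ``H_ij = 1`` iff dosage 1; ``W = H - 2pq``
    column-wise; ``K = W W' / sum 2 p_j q_j (1 - 2 p_j q_j)``.
    """
    if om.layer != "genomic":
        raise ValueError("dominance kernel is defined for genotype dosages only")
    M = om.values
    H = (M == 1.0).astype(float)
    if not np.any(H):
        raise ValueError("no heterozygous calls: dominance kernel undefined")
    p = M.mean(axis=0) / 2.0 if freq is None else np.asarray(freq, dtype=float)
    q = 1.0 - p
    denom = float(np.sum(2.0 * p * q * (1.0 - 2.0 * p * q)))
    if denom <= 0:
        raise ValueError("no intermediate-frequency markers: zero denominator")
    W = H - 2.0 * p * q
    K = (W @ W.T) / denom
    return _stabilized(K, "dominance", om.layer, om.individuals)


def epistatic_kernel(additive: RelationshipKernel) -> RelationshipKernel:
    """Second-order additive x additive kernel: Hadamard square of A,
    rescaled to mean diagonal 1. PSD by the Schur product theorem."""
    if additive.kind != "additive":
        raise ValueError("epistatic kernel must be built from an additive kernel")
    E = additive.matrix * additive.matrix
    E = E / np.mean(np.diag(E))
    return _stabilized(E, "epistatic", additive.layer, list(additive.ids))


def euclidean_distances(om: OmicsMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distance matrix between individuals."""
    M = om.values
    if np.any(~np.isfinite(M)):
        raise ValueError("missing values: impute before computing distances")
    D = squareform(pdist(M, metric="euclidean"))
    return DistanceMatrix(D, om.layer, om.individuals)


def gaussian_kernel(dist: DistanceMatrix, h: float) -> RelationshipKernel:
    """Gaussian kernel ``K_ij = exp(-h * d2_ij)`` on mean-scaled squared
    distances; unit diagonal by construction."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    K = np.exp(-h * dist.scaled_sq)
    return RelationshipKernel(K, "gaussian", dist.layer, list(dist.ids), bandwidth=float(h))


@dataclass
class BandwidthProfile:
    """REML log-likelihood profile over a bandwidth grid."""

    grid: list[float]
    loglik: list[float]
    best: float


def estimate_bandwidth(dist: DistanceMatrix, y: np.ndarray,
                       grid=DEFAULT_BANDWIDTH_GRID,
                       tie_tol: float = 1e-6) -> BandwidthProfile:
    """Pick the Gaussian bandwidth maximizing the single-kernel REML
    log-likelihood over a grid; ties (within ``tie_tol`` log-lik units)
    break toward the smallest h, i.e. the smoothest kernel."""
    from .reml import fit_reml  # local import to avoid a cycle

    grid = sorted(float(h) for h in grid)
    if not grid:
        raise ValueError("bandwidth grid is empty")
    y = np.asarray(y, dtype=float)
    if y.shape[0] != dist.n:
        raise ValueError("phenotype vector not aligned to distance matrix")
    logliks: list[float] = []
    for h in grid:
        K = gaussian_kernel(dist, h)
        try:
            fit = fit_reml(y, [K])
            logliks.append(fit.loglik)
        except Exception:
            logliks.append(-np.inf)
    arr = np.asarray(logliks)
    if not np.any(np.isfinite(arr)):
        raise RuntimeError("REML likelihood non-finite at every grid point")
    best_ll = np.nanmax(arr[np.isfinite(arr)])
    best = min(h for h, ll in zip(grid, logliks) if np.isfinite(ll) and ll >= best_ll - tie_tol)
    return BandwidthProfile(grid, logliks, best)


def _stabilized(K: np.ndarray, kind: str, layer: str, ids: list[str]) -> RelationshipKernel:
    """Symmetrize and, if slightly indefinite, add logged diagonal jitter."""
    K = 0.5 * (K + K.T)
    jitter = 0.0
    lam = float(np.linalg.eigvalsh(K)[0])
    if lam < RelationshipKernel.PSD_TOL:
        jitter = -lam + 1e-10
        warnings.warn(f"{kind} kernel indefinite (min eig {lam:.2e}); "
                      f"adding diagonal jitter {jitter:.2e}")
        K = K + jitter * np.eye(K.shape[0])
    return RelationshipKernel(K, kind, layer, ids, jitter=jitter)
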