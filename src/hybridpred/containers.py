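"""Core data containers shared across the pipeline.

The containers are thin, typed wrappers around pandas/numpy objects: an
omics layer is an individuals x features DataFrame plus a layer tag, a
cross plan is a table of (pollinator, tester) pairs, and a relationship
kernel is a symmetric PSD matrix together with the individual ordering it
indexes. They validate their own invariants on construction so downstream
code can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

LAYERS = ("genomic", "transcriptomic", "metabolic", "phenomic")
KERNEL_KINDS = ("additive", "dominance", "epistatic", "gaussian")


@dataclass
class OmicsMatrix:
    """Individuals x features numeric matrix with a layer tag.

    Parameters
    ----------
    data
        DataFrame with individual ids as index and feature ids as columns.
    layer
        One of ``genomic``, ``transcriptomic``, ``metabolic``, ``phenomic``.
    """

    data: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        # string labels throughout: keeps ids stable across file round-trips
        if not (self.data.index.dtype == object and self.data.columns.dtype == object):
            self.data = self.data.copy()
            self.data.index = self.data.index.astype(str)
            self.data.columns = self.data.columns.astype(str)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate individual ids in omics matrix")

    @property
    def individuals(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def features(self) -> list[str]:
        return list(self.data.columns.astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[:, list(feature_ids)], self.layer)

    def subset_individuals(self, ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[list(ids)], self.layer)


@dataclass
class CrossPlan:
    """Pollinator x tester pairs defining the hybrids of a factorial testcross.

    Hybrid ids are ``{pollinator}x{tester}`` unless given explicitly.
    """

    pairs: pd.DataFrame  # columns: pollinator, tester, hybrid

    def __post_init__(self) -> None:
        required = {"pollinator", "tester"}
        if not required.issubset(self.pairs.columns):
            raise ValueError("cross plan needs 'pollinator' and 'tester' columns")
        self.pairs = self.pairs.copy()
        if "hybrid" not in self.pairs.columns:
            self.pairs["hybrid"] = (
                self.pairs["pollinator"].astype(str) + "x" + self.pairs["tester"].astype(str)
            )
        if self.pairs["hybrid"].duplicated().any():
            raise ValueError("duplicate hybrid ids in cross plan")

    @classmethod
    def factorial(cls, pollinators: Sequence[str], testers: Sequence[str]) -> "CrossPlan":
        rows = [(p, t) for p in pollinators for t in testers]
        return cls(pd.DataFrame(rows, columns=["pollinator", "tester"]))

    @property
    def hybrids(self) -> list[str]:
        return list(self.pairs["hybrid"])

    @property
    def pollinators(self) -> list[str]:
        """Unique pollinators in plan order."""
        return list(dict.fromkeys(self.pairs["pollinator"]))

    @property
    def testers(self) -> list[str]:
        return list(dict.fromkeys(self.pairs["tester"]))

    def __len__(self) -> int:
        return len(self.pairs)

    def parents_of(self, hybrid: str) -> tuple[str, str]:
        row = self.pairs.loc[self.pairs["hybrid"] == hybrid]
        if row.empty:
            raise KeyError(f"unknown hybrid {hybrid!r}")
        return str(row["pollinator"].iloc[0]), str(row["tester"].iloc[0])

    def hybrids_of_pollinators(self, pollinators: Sequence[str]) -> list[str]:
        mask = self.pairs["pollinator"].isin(set(pollinators))
        return list(self.pairs.loc[mask, "hybrid"])


@dataclass
class RelationshipKernel:
    """n x n symmetric PSD relationship matrix with its individual ordering."""

    matrix: np.ndarray
    kind: str
    layer: str
    ids: list[str]
    bandwidth: float | None = None
    jitter: float = 0.0

    SYMMETRY_TOL = 1e-10
    PSD_TOL = -1e-8

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("kernel matrix shape does not match id count")
        asym = np.max(np.abs(self.matrix - self.matrix.T)) if n else 0.0
        if asym > self.SYMMETRY_TOL:
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:.2e})")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)
        if np.any(np.diag(self.matrix) <= 0):
            raise ValueError("kernel diagonal must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def check_psd(self) -> None:
        lam = self.min_eigenvalue()
        if lam < self.PSD_TOL:
            raise ValueError(f"kernel not PSD (min eigenvalue {lam:.2e})")

    def submatrix(self, rows: Sequence[str], cols: Sequence[str] | None = None) -> np.ndarray:
        """Cross block K[rows, cols] by individual id."""
        pos = {g: i for i, g in enumerate(self.ids)}
        ri = [pos[r] for r in rows]
        ci = ri if cols is None else [pos[c] for c in cols]
        return self.matrix[np.ix_(ri, ci)]

    def reorder(self, ids: Sequence[str]) -> "RelationshipKernel":
        sub = self.submatrix(list(ids), list(ids))
        return RelationshipKernel(sub, self.kind, self.layer, list(ids), self.bandwidth, self.jitter)


@dataclass
class DistanceMatrix:
    """Euclidean distance matrix between individuals for one omics layer.

    ``scaled_sq`` caches the squared distances divided by their off-diagonal
    mean, the quantity the Gaussian kernel exponentiates; the scaling keeps
    one bandwidth grid comparable across layers of very different dimension.
    """

    matrix: np.ndarray
    layer: str
    ids: list[str]
    scaled_sq: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match id count")
        if np.max(np.abs(np.diag(self.matrix))) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if np.min(self.matrix) < 0:
            raise ValueError("distances must be nonnegative")
        if self.scaled_sq is None:
            sq = self.matrix**2
            off = ~np.eye(n, dtype=bool)
            mean_off = sq[off].mean() if n > 1 else 1.0
            self.scaled_sq = sq / mean_off if mean_off > 0 else sq

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class MixedModelFit:
    """REML fit of a (multi-)kernel mixed model."""

    beta: np.ndarray                  # fixed effects (intercept first)
    variance_components: dict[str, float]   # per-kernel sigma^2_k
    residual_variance: float
    blups: dict[str, np.ndarray]      # per-kernel BLUP vector, aligned to ids
    loglik: float                     # restricted log-likelihood at the optimum
    ids: list[str]
    kernels: list[RelationshipKernel] | None = None
    iterations: int = 0
    converged: bool = False
    trace: list[float] = field(default_factory=list)
    floored: list[str] = field(default_factory=list)
    y: np.ndarray | None = None       # training response (for prediction)
    X: np.ndarray | None = None       # fixed-effect design

    @property
    def mu(self) -> float:
        return float(self.beta[0])


@dataclass
class CvResult:
    """Per-cycle Pearson accuracies for each predictor set, with the splits."""

    accuracies: pd.DataFrame          # rows: cycles, columns: predictor-set labels
    masked_pollinators: list[list[str]]
    seed: int
    model: str                       # "gblup" | "rkhs"
    trait: str = "trait"
    failed_cycles: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.accuracies.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("accuracies must lie in [-1, 1]")

    @property
    def sets(self) -> list[str]:
        return list(self.accuracies.columns)

    def mean_accuracy(self) -> pd.Series:
        return self.accuracies.mean(axis=0, skipna=True)
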