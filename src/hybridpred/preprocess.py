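"""Quantification-to-predictor preprocessing for the omics layers.

Transcripts: TPM normalization (per-sample rate = count/length, rescaled to
sum to 1e6) and a median-expression filter (median tpm >= 5 across samples
by default). Metabolites: blank-contamination filter (mean sample / mean
blank intensity strictly greater than 2), sample-weight and measuring-day
normalization, single-pass outlier removal at median +/- 4 SD, and a
Box-Cox power transform with per-feature lambda chosen by maximum
likelihood over a grid. Finally, predictor columns are min-max scaled to
the ranges the relationship kernels consume: [0, 2] for genotypes and
[0, 1] for transcripts and metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix

BOXCOX_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.05), 10)


@dataclass
class PreprocessReport:
    """Audit trail of the preprocessing filters."""

    steps: list[dict] = field(default_factory=list)
    boxcox_lambda: dict[str, float] = field(default_factory=dict)
    outlier_counts: dict[str, int] = field(default_factory=dict)
    constant_columns: dict[str, list[str]] = field(default_factory=dict)

    def record(self, step: str, features_in: int, features_out: int, **extra) -> None:
        if features_out > features_in:
            raise ValueError("a filter cannot add features")
        self.steps.append({"step": step, "features_in": features_in,
                           "features_out": features_out, **extra})

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "boxcox_lambda": self.boxcox_lambda,
            "outlier_counts": self.outlier_counts,
            "constant_columns": self.constant_columns,
        }


def tpm_normalize(counts: OmicsMatrix, lengths_kb: pd.Series) -> OmicsMatrix:
    """Transcripts-per-million: rate_f = count_f / length_f per individual,
    rescaled so every individual's row sums to 1e6."""
    lengths = lengths_kb.copy()
    lengths.index = lengths.index.astype(str)
    lengths = lengths.reindex(counts.features)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing transcript lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    C = counts.values
    if np.any(C < 0):
        raise ValueError("counts must be nonnegative")
    rates = C / lengths.to_numpy()[None, :]
    totals = rates.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        bad = [counts.individuals[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero total count for individual(s): {bad}")
    tpm = 1e6 * rates / totals[:, None]
    return OmicsMatrix(pd.DataFrame(tpm, index=counts.data.index,
                                    columns=counts.data.columns), counts.layer)


def filter_expressed(tpm: OmicsMatrix, threshold: float = 5.0,
                     report: PreprocessReport | None = None) -> OmicsMatrix:
    """Keep features whose across-individual median tpm is >= threshold."""
    med = np.median(tpm.values, axis=0)
    keep = med >= threshold
    if not np.any(keep):
        warnings.warn("expression filter removed every feature")
    out = tpm.subset_features([f for f, k in zip(tpm.features, keep) if k])
    if report is not None:
        report.record("filter_expressed", tpm.shape[1], out.shape[1],
                      threshold=threshold)
    return out


def filter_blanks(samples: OmicsMatrix, blanks: OmicsMatrix, ratio: float = 2.0,
                  report: PreprocessReport | None = None) -> OmicsMatrix:
    """Keep features whose mean sample intensity exceeds ``ratio`` times the
    mean blank intensity (strict >). Features absent from blanks and
    features with zero blank but nonzero sample signal are kept."""
    shared = [f for f in samples.features if f in set(blanks.features)]
    if not shared:
        raise ValueError("sample and blank feature sets are disjoint")
    s_mean = samples.data[shared].mean(axis=0).to_numpy()
    b_mean = blanks.data[shared].mean(axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        keep_shared = np.where(b_mean > 0, s_mean / b_mean > ratio, s_mean > 0)
    keep = {f for f, k in zip(shared, keep_shared) if k}
    keep |= set(samples.features) - set(blanks.features)
    out = samples.subset_features([f for f in samples.features if f in keep])
    if report is not None:
        report.record("filter_blanks", samples.shape[1], out.shape[1], ratio=ratio)
    return out


def remove_outliers(x: np.ndarray | pd.Series, k: float = 4.0) -> np.ndarray:
    """Single-pass outlier removal: values outside median +/- k * SD become
    NaN; the SD is the classical standard deviation of the non-missing
    values before removal."""
    arr = np.asarray(x, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() == 0:
        raise ValueError("all values missing")
    if finite.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    med = np.median(arr[finite])
    sd = np.std(arr[finite], ddof=1)
    out = arr.copy()
    mask = finite & (np.abs(arr - med) > k * sd)
    out[mask] = np.nan
    return out


def boxcox_transform(x: np.ndarray | pd.Series, lam: float | None = None,
                     grid: np.ndarray = BOXCOX_GRID) -> tuple[np.ndarray, float]:
    """Box-Cox power transform ``(x^lam - 1)/lam`` (log for lam = 0).

    When ``lam`` is None it is chosen by maximum likelihood over the grid.
    Non-positive inputs are shifted to positive with a logged offset.
    """
    arr = np.asarray(x, dtype=float)
    finite = np.isfinite(arr)
    vals = arr[finite]
    if vals.size == 0:
        raise ValueError("all values missing")
    if vals.min() <= 0:
        offset = -vals.min() + 1e-6 * max(np.ptp(vals), 1.0) + 1e-12
        warnings.warn(f"shifting by {offset:.4g} to make values positive")
        arr = arr + offset
        vals = vals + offset
        if vals.min() <= 0:
            raise ValueError("values non-positive after shift")
    if lam is None:
        lls = [stats.boxcox_llf(l, vals) for l in grid]
        lam = float(grid[int(np.argmax(lls))])
    out = np.full_like(arr, np.nan)
    if lam == 0:
        out[finite] = np.log(arr[finite])
    else:
        out[finite] = (arr[finite] ** lam - 1.0) / lam
    return out, float(lam)


def normalize_batches(samples: OmicsMatrix, sample_weight: pd.Series | None = None,
                      batch: pd.Series | None = None) -> OmicsMatrix:
    """Normalize intensities by sample weight, then median-centre each
    measuring-day batch per feature (in log-free intensity space)."""
    X = samples.data.copy().astype(float)
    if sample_weight is not None:
        w = sample_weight.reindex(X.index)
        if w.isna().any() or (w <= 0).any():
            raise ValueError("sample weights must be positive and complete")
        X = X.div(w, axis=0)
    if batch is not None:
        b = batch.reindex(X.index)
        grand = X.median(axis=0)
        for lvl, idx in X.groupby(b).groups.items():
            X.loc[idx] = X.loc[idx] - X.loc[idx].median(axis=0) + grand
    return OmicsMatrix(X, samples.layer)


def scale_predictors(om: OmicsMatrix, report: PreprocessReport | None = None) -> OmicsMatrix:
    """Min-max scale each column to the range its kernel expects: [0, 2]
    for the genomic layer, [0, 1] otherwise. Constant columns map to the
    midpoint and are flagged in the report."""
    hi = 2.0 if om.layer == "genomic" else 1.0
    X = om.values.astype(float)
    mn, mx = np.nanmin(X, axis=0), np.nanmax(X, axis=0)
    span = mx - mn
    constant = span == 0
    span_safe = np.where(constant, 1.0, span)
    scaled = (X - mn) / span_safe * hi
    scaled[:, constant] = hi / 2.0
    if report is not None and np.any(constant):
        cols = [f for f, c in zip(om.features, constant) if c]
        report.constant_columns[om.layer] = cols
    out = pd.DataFrame(scaled, index=om.data.index, columns=om.data.columns)
    return OmicsMatrix(out, om.layer)


def preprocess_metabolites(samples: OmicsMatrix, blanks: OmicsMatrix | None = None,
                           sample_weight: pd.Series | None = None,
                           batch: pd.Series | None = None,
                           blank_ratio: float = 2.0, outlier_sd: float = 4.0,
                           report: PreprocessReport | None = None) -> OmicsMatrix:
    """Full metabolite chain: blank filter -> weight/day normalization ->
    outlier removal -> per-feature Box-Cox."""
    if report is None:
        report = PreprocessReport()
    out = samples
    if blanks is not None:
        out = filter_blanks(out, blanks, blank_ratio, report)
    out = normalize_batches(out, sample_weight, batch)
    X = out.data.copy()
    for f in X.columns:
        cleaned = remove_outliers(X[f].to_numpy(), outlier_sd)
        n_rm = int(np.sum(np.isfinite(X[f].to_numpy()) & ~np.isfinite(cleaned)))
        if n_rm:
            report.outlier_counts[str(f)] = n_rm
        transformed, lam = boxcox_transform(cleaned)
        report.boxcox_lambda[str(f)] = lam
        X[f] = transformed
    report.record("preprocess_metabolites", samples.shape[1], X.shape[1])
    return OmicsMatrix(X, out.layer)
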