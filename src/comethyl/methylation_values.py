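"""β/M-value conversions, missingness QC, and between-sample normalization.

The methylation fraction at a CpG is summarized either as a β value,
``β = M_int / (M_int + U_int + α)`` with the array's offset ``α`` (default
100), or on the logit scale as an M value, ``M = log2(β / (1 − β))``. β is
bounded and interpretable; M is unbounded and variance-stabilized, so all
test statistics and network correlations downstream operate on M while effect
sizes are reported as Δβ.

Between-sample normalization is classic quantile normalization: every sample
is forced onto the common distribution of row-wise means of the sorted
columns. It is exposed both as :func:`quantile_normalize` and as the
sklearn-style :class:`QuantileNormalizer` transformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .core_io import MethylationMatrix, SignalIntensities

__all__ = [
    "QCReport",
    "compute_beta",
    "beta_to_m",
    "m_to_beta",
    "qc_filter",
    "quantile_normalize",
    "quantile_normalize_intensities",
    "QuantileNormalizer",
    "DEFAULT_EPSILON",
]

#: default clipping constant for the logit transform
DEFAULT_EPSILON = 1e-6


@dataclass
class QCReport:
    """Record of probes/samples removed or imputed during quality filtering."""

    dropped_probes: dict[str, str] = field(default_factory=dict)  # probe → reason
    dropped_samples: dict[str, str] = field(default_factory=dict)
    imputed: dict[str, int] = field(default_factory=dict)  # probe → n entries imputed
    notes: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_probes)

    def is_empty(self) -> bool:
        return not (self.dropped_probes or self.dropped_samples or self.imputed or self.notes)


def compute_beta(intensities: SignalIntensities) -> MethylationMatrix:
    """β = M_int / (M_int + U_int + α), elementwise.

    The denominator is at least α, so with α > 0 the output is strictly below
    1. With α = 0 and both channels zero the value is defined as 0.
    """
    m = intensities.meth.to_numpy(dtype=float)
    u = intensities.unmeth.to_numpy(dtype=float)
    denom = m + u + intensities.alpha
    with np.errstate(invalid="ignore"):
        beta = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), 0.0)
    values = pd.DataFrame(beta, index=intensities.meth.index, columns=intensities.meth.columns)
    return MethylationMatrix(values, scale="beta")


def beta_to_m(matrix: MethylationMatrix, epsilon: float = DEFAULT_EPSILON) -> MethylationMatrix:
    """Logit conversion M = log2(β / (1 − β)), with β clipped to [ε, 1 − ε]."""
    if matrix.scale != "beta":
        raise ValueError(f"expected a β-scale matrix, got scale={matrix.scale!r}")
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    beta = matrix.values.to_numpy(dtype=float)
    clipped = np.clip(beta, epsilon, 1.0 - epsilon)
    m = np.log2(clipped / (1.0 - clipped))
    m = np.where(np.isnan(beta), np.nan, m)
    return MethylationMatrix(
        pd.DataFrame(m, index=matrix.values.index, columns=matrix.values.columns), scale="m"
    )


def m_to_beta(matrix: MethylationMatrix) -> MethylationMatrix:
    """Inverse logit β = 2^M / (1 + 2^M)."""
    if matrix.scale != "m":
        raise ValueError(f"expected an M-scale matrix, got scale={matrix.scale!r}")
    m = matrix.values.to_numpy(dtype=float)
    # expit form avoids overflow for large |M|
    beta = 1.0 / (1.0 + np.exp2(-m))
    return MethylationMatrix(
        pd.DataFrame(beta, index=matrix.values.index, columns=matrix.values.columns),
        scale="beta",
    )


def qc_filter(
    matrix: MethylationMatrix, max_missing_fraction: float = 0.05, impute: bool = True
) -> tuple[MethylationMatrix, QCReport]:
    """Drop probes with too many missing entries; impute the rest by probe median.

    A probe whose missing fraction exceeds ``max_missing_fraction`` is dropped.
    Remaining missing entries are replaced by the probe's median across samples
    (set ``impute=False`` to drop any incomplete probe instead).
    """
    report = QCReport()
    values = matrix.values
    frac_missing = values.isna().mean(axis=1)
    if impute:
        drop = frac_missing > max_missing_fraction
    else:
        drop = frac_missing > 0
    for probe in values.index[drop]:
        report.dropped_probes[probe] = (
            f"missing fraction {frac_missing[probe]:.3f} > {max_missing_fraction}"
            if impute
            else "incomplete probe"
        )
    kept = values.loc[~drop].copy()
    if kept.empty:
        raise ValueError("QC removed every probe")
    if impute:
        incomplete = kept.isna().any(axis=1)
        for probe in kept.index[incomplete]:
            n_missing = int(kept.loc[probe].isna().sum())
            kept.loc[probe] = kept.loc[probe].fillna(kept.loc[probe].median())
            report.imputed[probe] = n_missing
    return MethylationMatrix(kept, matrix.scale), report


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Classic quantile normalization as an sklearn transformer.

    Following the sklearn convention ``X`` is (n_samples, n_features); fitting
    stores the reference distribution — the mean across samples of each
    sample's sorted feature values — and transforming maps every sample's
    ranks onto it, ties sharing the mean of their target values.
    """

    def fit(self, X, y=None):
        X = self._validate(X)
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        out = np.empty_like(X, dtype=float)
        grid = np.arange(1, self.n_features_in_ + 1, dtype=float)
        for i, row in enumerate(X):
            # average rank → interpolate into the reference so ties share means
            ranks = rankdata(row, method="average")
            out[i] = np.interp(ranks, grid, self.reference_)
        return out

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples × features)")
        if np.isnan(X).any():
            raise ValueError("quantile normalization requires a complete matrix")
        return X


def quantile_normalize(matrix: MethylationMatrix) -> MethylationMatrix:
    """Quantile-normalize samples of a probes × samples matrix.

    Every sample column is mapped onto the common distribution of row-wise
    means of the sorted columns. A single-sample matrix is returned unchanged
    with a warning.
    """
    values = matrix.values
    if values.shape[1] < 2:
        warnings.warn("single-sample matrix: quantile normalization is the identity")
        return MethylationMatrix(values.copy(), matrix.scale)
    normalized = QuantileNormalizer().fit_transform(values.to_numpy(dtype=float).T).T
    return MethylationMatrix(
        pd.DataFrame(normalized, index=values.index, columns=values.columns), matrix.scale
    )


def quantile_normalize_intensities(intensities: SignalIntensities) -> SignalIntensities:
    """Quantile-normalize both channels jointly.

    The methylated and unmethylated rows of each sample are stacked into one
    long vector per sample before normalizing, so the two channels share a
    common target distribution — the matrix-level analogue of normalizing raw
    signal before computing β.
    """
    stacked = pd.concat([intensities.meth, intensities.unmeth], axis=0, ignore_index=True)
    norm = QuantileNormalizer().fit_transform(stacked.to_numpy(dtype=float).T).T
    n = intensities.meth.shape[0]
    meth = pd.DataFrame(norm[:n], index=intensities.meth.index, columns=intensities.meth.columns)
    unmeth = pd.DataFrame(
        norm[n:], index=intensities.unmeth.index, columns=intensities.unmeth.columns
    )
    return SignalIntensities(meth, unmeth, intensities.alpha)
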