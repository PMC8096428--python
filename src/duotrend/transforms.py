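"""Normalization and variable transforms applied before testing.

Expression matrices enter the trend tests and the mediation scan only after
a per-feature rank-based inverse normal transform, which suppresses the
influence of outliers that are unavoidable in large cohorts.  Raw RNA-seq
counts are depth-normalized with median-of-ratios size factors before model
fitting, and urinary analytes are adjusted for urinary creatinine (a proxy
for urine concentration) before use as phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NormalizedMatrix:
    """A features x samples real-valued matrix with a transform descriptor."""

    values: pd.DataFrame
    method: str
    params: dict = field(default_factory=dict)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def rank_normal_transform(x, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse normal scores of a vector.

    Maps value ``x_i`` with mid-rank ``r_i`` to
    ``Phi^-1((r_i - offset) / (n - 2*offset + 1))``.  With the default
    ``offset=0.5`` the quantiles are ``(r - 0.5)/n``; ``offset=0.375``
    gives Blom scores.  Ties receive mid-ranks and hence equal scores.

    Parameters
    ----------
    x : array-like of shape (n,)
        Input values, n >= 3.  Must not be constant.
    offset : float in [0, 0.5]
        Quantile offset constant.

    Returns
    -------
    numpy.ndarray
        Normal scores, same order as the input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("rank_normal_transform expects a 1-D vector")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if not (0.0 <= offset <= 0.5):
        raise ValueError(f"offset must lie in [0, 0.5], got {offset}")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: no ordering information")
    r = stats.rankdata(x, method="average")
    q = (r - offset) / (n - 2.0 * offset + 1.0)
    return stats.norm.ppf(q)


def rank_normal_matrix(matrix: pd.DataFrame, offset: float = 0.5) -> NormalizedMatrix:
    """Apply :func:`rank_normal_transform` to every row of a features x samples table.

    Constant rows cannot be scored and are dropped (they carry no ordering
    information for any downstream test).
    """
    keep = matrix.apply(lambda row: np.ptp(row.to_numpy(dtype=float)) > 0, axis=1)
    sub = matrix.loc[keep]
    out = sub.apply(
        lambda row: pd.Series(rank_normal_transform(row.to_numpy(dtype=float), offset), index=sub.columns),
        axis=1,
    )
    return NormalizedMatrix(out, method="rank_normal", params={"offset": offset, "dropped_constant": int((~keep).sum())})


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors for a genes x samples count matrix.

    For each gene expressed in every sample (the reference set), compute the
    ratio of its count in sample *j* to its geometric mean across samples;
    the sample's factor is the median of these ratios, rescaled so the
    factors have geometric mean 1.
    """
    c = counts.to_numpy(dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    ref = (c > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; filter low-coverage genes before size-factor estimation"
        )
    logc = np.log(c[ref])
    log_geomean = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geomean, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def variance_stabilize(
    counts: pd.DataFrame, size_factors: pd.Series, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Shifted-log transform of depth-normalized counts.

    Returns ``log2(count / size_factor + pseudocount)``, a monotone
    variance-flattening transform suitable ahead of PCA-style analyses.
    """
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise ValueError("size factors must be positive and cover every sample")
    vals = np.log2(counts.to_numpy(dtype=float) / sf + pseudocount)
    out = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    return NormalizedMatrix(out, method="shifted_log2", params={"pseudocount": pseudocount})


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample by its upper quartile of nonzero counts (library-size correction)."""
    c = counts.to_numpy(dtype=float)
    uq = np.array([np.percentile(col[col > 0], 75) if (col > 0).any() else np.nan for col in c.T])
    if np.any(~np.isfinite(uq)) or np.any(uq <= 0):
        raise ValueError("every sample needs nonzero counts for upper-quartile normalization")
    scaled = c / uq * np.exp(np.mean(np.log(uq)))
    return pd.DataFrame(scaled, index=counts.index, columns=counts.columns)


def adjust_urine_analyte(
    analyte,
    creatinine,
    method: str = "residual",
    floor: float | None = None,
) -> np.ndarray:
    """Adjust a urinary analyte for urinary creatinine (urine-concentration proxy).

    method="ratio"    -> log(analyte / creatinine)
    method="residual" -> residuals of log(analyte) regressed on log(creatinine)

    Values at or below zero (below-detection readings) raise unless ``floor``
    is given, in which case they are clamped to ``floor`` before the log.
    """
    a = np.asarray(analyte, dtype=float)
    cr = np.asarray(creatinine, dtype=float)
    if a.shape != cr.shape or a.ndim != 1:
        raise ValueError("analyte and creatinine must be 1-D vectors of equal length")
    if floor is not None:
        a = np.maximum(a, floor)
    if np.any(a <= 0) or np.any(cr <= 0):
        raise ValueError("non-positive values present; pass a detection floor")
    la, lc = np.log(a), np.log(cr)
    if method == "ratio":
        return la - lc
    if method == "residual":
        X = np.column_stack([np.ones_like(lc), lc])
        beta, *_ = np.linalg.lstsq(X, la, rcond=None)
        return la - X @ beta
    raise ValueError(f"unknown method {method!r}; use 'ratio' or 'residual'")
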