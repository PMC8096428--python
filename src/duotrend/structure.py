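"""Sources-of-variation analyses: PCA, marker-based deconvolution, ORA.

PCA on rank-normal expression partitions sample-level variance and each
component's scores are regressed on age and sex to attribute the major axes
of variation.  Marker-based deconvolution summarizes each cell type's marker
genes in bulk data as a surrogate proportion variable (SPV) — the first
principal component of the standardized marker submatrix — which tracks
relative cell-type abundance without an explicit mixture model.  A
hypergeometric over-representation test covers gene-set enrichment against
user-supplied annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trendtest import bh_adjust, build_design

__all__ = [
    "PCAResult",
    "pca_variance",
    "pc_association",
    "select_markers",
    "compute_spv",
    "spv_table",
    "ora_hypergeometric",
]


@dataclass
class PCAResult:
    variance_fraction: np.ndarray      # all components, non-increasing
    scores: pd.DataFrame               # samples x top-k components
    loadings: pd.DataFrame             # features x top-k components


def pca_variance(matrix: pd.DataFrame, k: int) -> PCAResult:
    """PCA of a features x samples matrix over samples, with sign-fixed scores.

    Features are centered across samples (no rescaling: rank-normal input is
    already on a common scale); variance fractions come from the squared
    singular values.  Each component's sign is fixed so the feature with the
    largest absolute loading has a positive loading.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x features
    n, p = X.shape
    if k < 1 or k > min(n, p):
        raise ValueError(f"k={k} outside [1, {min(n, p)}]")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    # sign convention
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    comp = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=matrix.columns, columns=comp)
    loadings = pd.DataFrame(Vt[:k].T, index=matrix.index, columns=comp)
    return PCAResult(variance_fraction=frac, scores=scores, loadings=loadings)


def pc_association(scores, covariate) -> float:
    """F-test p-value of a linear model score ~ covariate.

    A numeric covariate (e.g. coded age) enters as a linear term; a
    categorical one (e.g. sex) as a factor.
    """
    y = np.asarray(scores, dtype=float)
    cov = pd.Series(covariate)
    if cov.nunique() < 2:
        raise ValueError("constant covariate")
    if pd.api.types.is_numeric_dtype(cov):
        X = np.column_stack([np.ones(len(y)), cov.to_numpy(dtype=float)])
    else:
        d = pd.get_dummies(cov.astype("category"), drop_first=True, dtype=float)
        X = np.column_stack([np.ones(len(y)), d.to_numpy()])
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    df1, df2 = p - 1, n - p
    if rss <= 0:
        return 0.0
    f = ((tss - rss) / df1) / (rss / df2)
    return float(stats.f.sf(f, df1, df2))


def select_markers(
    reference: pd.DataFrame, max_markers: int = 50, min_ratio: float = 2.0
) -> dict[str, list[str]]:
    """Pick cell-type marker genes from a genes x cell-types mean-profile matrix.

    A gene qualifies as a marker of the type where its mean is highest if
    that mean exceeds the second-highest type by at least ``min_ratio``-fold;
    per type, the ``max_markers`` genes with the largest ratios are kept.
    Types with no qualifying marker are dropped (with a warning via the
    returned empty entry being omitted).
    """
    if reference.shape[1] < 2:
        raise ValueError("need at least 2 cell types to discriminate markers")
    vals = reference.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("reference profiles must be non-negative")
    eps = 1e-9
    order = np.argsort(vals, axis=1)
    top_idx = order[:, -1]
    top = vals[np.arange(len(vals)), top_idx]
    second = vals[np.arange(len(vals)), order[:, -2]]
    ratio = top / (second + eps)
    markers: dict[str, list[str]] = {}
    for t, tname in enumerate(reference.columns):
        mask = (top_idx == t) & (ratio >= min_ratio)
        if not mask.any():
            continue
        idx = np.where(mask)[0]
        idx = idx[np.argsort(-ratio[idx], kind="mergesort")][:max_markers]
        markers[str(tname)] = [str(g) for g in reference.index[idx]]
    return markers


def compute_spv(
    bulk: pd.DataFrame, markers: dict[str, list[str]], cell_type: str,
    metadata: pd.DataFrame | None = None,
) -> dict:
    """Surrogate proportion variable for one cell type in bulk expression.

    The SPV is the first principal component of the per-gene standardized
    marker x sample submatrix ("raw" extraction: no covariates are regressed
    out first, so downstream age-trend tests are untouched by the
    extraction), sign-oriented to correlate positively with the mean
    standardized marker signal, then standardized to mean 0 / SD 1.  If
    ``metadata`` is given an age-trend p (SPV ~ age_coded + sex) is included.
    """
    if cell_type not in markers:
        raise KeyError(f"no markers for cell type {cell_type!r}")
    present = [g for g in markers[cell_type] if g in bulk.index]
    if len(present) < 2:
        raise ValueError(f"fewer than 2 markers of {cell_type!r} present in bulk matrix")
    sub = bulk.loc[present].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mean) / sd
    U, s, Vt = np.linalg.svd(z, full_matrices=False)
    spv = Vt[0]
    signal = z.mean(axis=0)
    if np.corrcoef(spv, signal)[0, 1] < 0:
        spv = -spv
    spv = (spv - spv.mean()) / spv.std()
    out = {"cell_type": cell_type, "n_markers": len(present),
           "spv": pd.Series(spv, index=bulk.columns, name=cell_type)}
    if metadata is not None:
        X_full, X_red, _ = build_design(metadata.loc[bulk.columns], "age_coded", ("sex",))
        out["trend_p"] = _age_p(spv, X_full, X_red)
    return out


def _age_p(y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray) -> float:
    n = y.shape[0]
    rss_f = _rss(y, X_full)
    rss_r = _rss(y, X_red)
    lrt = max(n * (np.log(rss_r) - np.log(rss_f)), 0.0)
    return float(stats.chi2.sf(lrt, df=1))


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def spv_table(
    bulk: pd.DataFrame, markers: dict[str, list[str]], metadata: pd.DataFrame
) -> pd.DataFrame:
    """SPVs and BH-adjusted age-trend p-values for every cell type with markers.

    Returns one row per usable cell type: cell_type, n_markers, trend_p,
    trend_q, then one column per sample.
    """
    rows = []
    for ct in markers:
        try:
            res = compute_spv(bulk, markers, ct, metadata)
        except ValueError:
            continue
        rows.append(res)
    if not rows:
        raise ValueError("no cell type had >=2 markers present in the bulk matrix")
    table = pd.DataFrame({
        "cell_type": [r["cell_type"] for r in rows],
        "n_markers": [r["n_markers"] for r in rows],
        "trend_p": [r["trend_p"] for r in rows],
    })
    table["trend_q"] = bh_adjust(table["trend_p"].to_numpy())
    spvs = pd.DataFrame([r["spv"] for r in rows]).reset_index(drop=True)
    return pd.concat([table, spvs], axis=1)


def ora_hypergeometric(selected, category, universe) -> tuple[int, float]:
    """One-sided hypergeometric over-representation test.

    Given a selected gene set and an annotation category, both inside a
    finite universe, returns ``(overlap, P(X >= overlap))`` where X is
    hypergeometric with population |universe|, |category| successes, and
    |selected| draws.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    category = set(category) & universe
    overlap = len(selected & category)
    M, K, N = len(universe), len(category), len(selected)
    p = float(stats.hypergeom.sf(overlap - 1, M, K, N))
    return overlap, min(p, 1.0)
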