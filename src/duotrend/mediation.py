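"""Nested-regression mediation analysis.

The transcriptome-wide scan asks, gene by gene, whether the age (or sex)
effect on a protein is carried by its mRNA: the focal term's significance is
compared between ``Protein ~ Age + Sex + Generation`` and
``Protein ~ mRNA + Age + Sex + Generation`` (ordinary least squares, inputs
on the rank-normal scale).  A drop in -log10 p after adding mRNA —
``delta = base - adjusted`` systematically positive — is the signature of
transcriptional mediation; points hugging the identity line mean the protein
effect is independent of mRNA.

The same nested logic applies to a single urinary phenotype and a candidate
mediator protein, and a covariate-adjusted partial correlation quantifies
phenotype-protein association.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .trendtest import build_design

__all__ = [
    "mediation_scan",
    "mediation_summary",
    "partial_correlation",
    "phenotype_mediation_test",
]


def _ols_focal_lrt_p(y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray) -> float:
    """LRT p-value (chi2, 1 df) for the focal column of a Gaussian OLS model."""
    n = y.shape[0]
    rss_f = _rss(y, X_full)
    rss_r = _rss(y, X_red)
    # reduced model already fits to rounding error (e.g. the response is a
    # column of the design): the focal term can add nothing
    if rss_r <= 1e-10 * max(float(y @ y), 1.0):
        return 1.0
    lrt = max(n * (np.log(rss_r) - np.log(rss_f)), 0.0)
    return float(stats.chi2.sf(lrt, df=1))


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def mediation_scan(
    protein: pd.DataFrame,
    mrna: pd.DataFrame,
    metadata: pd.DataFrame,
    focal: str = "age_coded",
    covariates: tuple[str, ...] = ("sex", "generation"),
) -> pd.DataFrame:
    """Per-gene focal-effect significance on protein without and with mRNA.

    Both matrices are genes x samples on the rank-normal scale and must share
    sample columns; genes present on only one platform are skipped.  When
    ``focal="sex"`` the age term stays in the model as a covariate, and vice
    versa.  Returns columns gene_id, focal, neglog10_p_base, neglog10_p_adj,
    delta, fit_flag.
    """
    samples = metadata.index
    if not (set(samples) <= set(protein.columns) and set(samples) <= set(mrna.columns)):
        raise ValueError("metadata samples missing from a matrix")
    cov = tuple(c for c in covariates if c != focal)
    if focal == "age_coded" and "sex" not in cov:
        cov = ("sex",) + cov
    if focal == "sex" and "age_coded" not in cov:
        cov = ("age_coded",) + cov
    X_full, X_red, _ = build_design(metadata, focal, cov)
    # move focal next to the front so mRNA can be appended/removed cleanly:
    # base model = [X_red | focal]; adjusted model adds the mRNA column.
    focal_col = X_full[:, -1:]
    shared = protein.index.intersection(mrna.index)
    skipped = protein.index.symmetric_difference(mrna.index)
    rows = []
    prot = protein.loc[shared, samples].to_numpy(dtype=float)
    rna = mrna.loc[shared, samples].to_numpy(dtype=float)
    for i, g in enumerate(shared):
        y = prot[i]
        m = rna[i][:, None]
        base_full = np.hstack([X_red, focal_col])
        adj_red = np.hstack([X_red, m])
        adj_full = np.hstack([X_red, m, focal_col])
        flag = "ok"
        try:
            if np.linalg.matrix_rank(adj_full) < adj_full.shape[1]:
                raise np.linalg.LinAlgError("rank-deficient design")
            p_base = _ols_focal_lrt_p(y, base_full, X_red)
            p_adj = _ols_focal_lrt_p(y, adj_full, adj_red)
            nb, na = -np.log10(max(p_base, 1e-300)), -np.log10(max(p_adj, 1e-300))
            delta = nb - na
        except np.linalg.LinAlgError:
            nb = na = delta = np.nan
            flag = "rank_deficient"
        rows.append({"gene_id": g, "focal": focal, "neglog10_p_base": nb,
                     "neglog10_p_adj": na, "delta": delta, "fit_flag": flag})
    table = pd.DataFrame(rows)
    table.attrs["n_skipped_unmatched"] = len(skipped)
    return table


def mediation_summary(records: pd.DataFrame, delta0: float = 0.5) -> dict:
    """Summarize a scan: median delta, tail fraction, and identity-line slope.

    The slope is the major axis (first principal component) of the
    (base, adjusted) -log10 p pairs; a slope near 1 with median delta near 0
    means the focal effect is untouched by adjusting for mRNA.
    """
    ok = records.dropna(subset=["delta"])
    if len(ok) < 10:
        raise ValueError("need >=10 converged records to summarize")
    delta = ok["delta"].to_numpy(dtype=float)
    x = ok["neglog10_p_base"].to_numpy(dtype=float)
    y = ok["neglog10_p_adj"].to_numpy(dtype=float)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        slope = 1.0
    else:
        cov = np.cov(np.vstack([x, y]))
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, np.argmax(evals)]
        slope = float(v[1] / v[0]) if v[0] != 0 else np.inf
    return {
        "n": int(len(ok)),
        "median_delta": float(np.median(delta)),
        "fraction_delta_gt": float(np.mean(delta > delta0)),
        "delta0": delta0,
        "major_axis_slope": slope,
    }


def partial_correlation(x, y, covariates) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariate effects.

    Both vectors are residualized on the covariate design (an intercept is
    added if absent); the p-value uses a t reference with
    n - rank(covariates) - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = x.shape[0]
    if y.shape[0] != n or C.shape[0] != n:
        raise ValueError("x, y and covariates must share length")
    has_const = np.any(np.ptp(C, axis=0) == 0)
    if not has_const:
        C = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        raise ValueError("rank-deficient covariate design")
    if n <= rank + 2:
        raise ValueError("too few observations for the covariate design")
    Q, _ = np.linalg.qr(C)
    rx = x - Q @ (Q.T @ x)
    ry = y - Q @ (Q.T @ y)
    # a residual that vanishes to rounding error means the variable is fully
    # explained by the covariates: no partial association is left
    tol = 1e-12
    if (rx @ rx) <= tol * max(float(x @ x), 1.0) or (ry @ ry) <= tol * max(float(y @ y), 1.0):
        return 0.0, 1.0
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - rank - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df))


def phenotype_mediation_test(
    phenotype,
    protein_row,
    metadata: pd.DataFrame,
    phenotype_name: str = "phenotype",
    protein_id: str = "protein",
) -> dict:
    """Age-term p for a phenotype before and after adjusting for a protein.

    Fits ``Phenotype ~ Age + Sex`` and ``Phenotype ~ Protein + Age + Sex``
    (OLS, LRT on the age term) and reports both p-values together with the
    sex-adjusted partial correlation of phenotype and protein.  Evidence of
    mediation is a small first p with a clearly larger second; both numbers
    are reported, no dichotomous verdict is forced.
    """
    y = np.asarray(phenotype, dtype=float)
    prot = np.asarray(protein_row, dtype=float)
    if y.shape[0] != len(metadata) or prot.shape[0] != len(metadata):
        raise ValueError("phenotype/protein misaligned with metadata")
    X_full, X_red, _ = build_design(metadata, "age_coded", ("sex",))
    focal_col = X_full[:, -1:]
    p_base = _ols_focal_lrt_p(y, X_full, X_red)
    with_prot_red = np.hstack([X_red, prot[:, None]])
    with_prot_full = np.hstack([X_red, prot[:, None], focal_col])
    if np.ptp(prot) == 0:
        # constant protein adds no information; both models coincide
        p_adj = p_base
        r, rp = np.nan, np.nan
    else:
        p_adj = _ols_focal_lrt_p(y, with_prot_full, with_prot_red)
        sex_ind = (metadata["sex"] == metadata["sex"].iloc[0]).to_numpy(dtype=float)
        r, rp = partial_correlation(y, prot, sex_ind[:, None])
    return {
        "phenotype": phenotype_name,
        "protein_id": protein_id,
        "partial_r": r,
        "partial_r_p": rp,
        "p_age_base": p_base,
        "p_age_with_protein": p_adj,
    }
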