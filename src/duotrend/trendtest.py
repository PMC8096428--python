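"""Per-feature likelihood-ratio trend tests with multiple-testing correction.

Age enters every model as a single ordered covariate coded (-0.5, 0, 0.5)
for the 6/12/18-month groups, so a one-degree-of-freedom likelihood-ratio
test of that coefficient is a linear trend test, and the coefficient itself
is an effect per year (the coded span of 1 unit covers 12 months).  Counts
are tested with a negative-binomial log-link GLM carrying a log size-factor
offset; protein abundances (rank-normal scale) are tested with a linear
mixed model carrying random intercepts for the mass-spec labeling tag and
the DO generation.  The same machinery tests sex differences by swapping
the focal term.

Two multiple-testing families are reported per result table: a stringent
family-wise Holm adjustment and a Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)

__all__ = [
    "ModelSpec",
    "TrendResult",
    "nb_trend_lrt",
    "lmm_trend_lrt",
    "nb_trend_table",
    "lmm_trend_table",
    "attach_adjustments",
    "holm_adjust",
    "bh_adjust",
    "trend_power",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which term is tested and which covariates/random factors are carried.

    focal : name of the tested metadata column ("age_coded" or "sex").
    covariates : fixed-effect columns kept in both nested models.
    random : metadata columns entering as random intercepts (LMM only).
    """

    focal: str = "age_coded"
    covariates: tuple[str, ...] = ("sex",)
    random: tuple[str, ...] = ()

    def __post_init__(self):
        if self.focal in self.covariates:
            raise ValueError(f"focal term {self.focal!r} duplicated in covariates")

    def with_focal(self, focal: str) -> "ModelSpec":
        cov = tuple(c for c in self.covariates if c != focal)
        if self.focal not in cov and self.focal != focal:
            cov = cov + (self.focal,)
        return replace(self, focal=focal, covariates=cov)


#: mRNA default — age trend adjusted for sex and sequencing batch.
MRNA_SPEC = ModelSpec(focal="age_coded", covariates=("sex", "batch"))
#: protein default — age trend adjusted for sex, random intercepts for tag and generation.
PROTEIN_SPEC = ModelSpec(focal="age_coded", covariates=("sex",), random=("tag", "generation"))


@dataclass
class TrendResult:
    """One feature's trend-test summary.

    estimate is in log2 units per year for count models and in coded-age
    units on the rank-normal scale for mixed models; z = estimate / se.
    """

    feature_id: str
    estimate: float = np.nan
    se: float = np.nan
    lrt: float = np.nan
    p: float = np.nan
    z: float = np.nan
    fit_flag: str = "ok"
    extra: dict = field(default_factory=dict)


def _encode_column(values: pd.Series) -> np.ndarray | pd.DataFrame:
    """Numeric column -> itself; categorical -> drop-first dummy block."""
    if pd.api.types.is_numeric_dtype(values):
        return values.to_numpy(dtype=float)
    dummies = pd.get_dummies(values.astype("category"), drop_first=True, dtype=float)
    if dummies.shape[1] == 0:
        raise ValueError(f"covariate {values.name!r} has fewer than 2 levels")
    return dummies


def build_design(metadata: pd.DataFrame, focal: str, covariates) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return (X_full, X_reduced, column names); the focal block comes last.

    The reduced design drops the focal block only, so the LRT df equals the
    number of focal columns (1 for age_coded or a 2-level sex factor).
    """
    cols: list[np.ndarray] = [np.ones(len(metadata))]
    names = ["intercept"]
    for cov in covariates:
        enc = _encode_column(metadata[cov])
        if isinstance(enc, pd.DataFrame):
            for c in enc.columns:
                cols.append(enc[c].to_numpy())
                names.append(f"{cov}[{c}]")
        else:
            cols.append(enc)
            names.append(cov)
    n_reduced = len(cols)
    enc = _encode_column(metadata[focal])
    if isinstance(enc, pd.DataFrame):
        if enc.shape[1] != 1:
            raise ValueError(f"focal term {focal!r} must contribute a single column")
        cols.append(enc.iloc[:, 0].to_numpy())
        names.append(f"{focal}[{enc.columns[0]}]")
    else:
        cols.append(enc)
        names.append(focal)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular fixed-effect design; columns: {names}")
    return X, X[:, :n_reduced], names


# ---------------------------------------------------------------------------
# negative-binomial GLM trend test
# ---------------------------------------------------------------------------


def _glm_nb_fit(y, X, offset, alpha):
    fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-12))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=200, tol=1e-9)


def nb_trend_lrt(
    counts_row,
    size_factors,
    metadata: pd.DataFrame,
    spec: ModelSpec = MRNA_SPEC,
    dispersion: float | None = None,
    feature_id: str = "",
) -> TrendResult:
    """Likelihood-ratio trend test for one gene's counts.

    Fits a negative-binomial log-link GLM with a log size-factor offset under
    the full and reduced (focal term dropped) designs.  The gene-wise
    dispersion alpha (Var = mu + alpha*mu^2) is estimated by maximum
    likelihood under the full model — profiled over a bounded log-alpha grid
    — and shared by both fits, unless ``dispersion`` pins it.

    Non-convergent or all-zero rows return a flagged result with NaN
    statistics rather than raising.
    """
    y = np.asarray(counts_row, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    if np.any(sf <= 0):
        raise ValueError("size factors must be positive")
    if y.shape[0] != len(metadata):
        raise ValueError("counts row and metadata are misaligned")
    X, Xr, _ = build_design(metadata, spec.focal, spec.covariates)
    if y.shape[0] < X.shape[1] + 2:
        raise ValueError("too few samples for the requested model")
    res = TrendResult(feature_id=feature_id)
    if not np.any(y > 0):
        res.fit_flag = "all_zero"
        return res
    offset = np.log(sf)
    try:
        if dispersion is None:
            def negll(log_alpha: float) -> float:
                try:
                    return -_glm_nb_fit(y, X, offset, np.exp(log_alpha)).llf
                except Exception:
                    return 1e12
            opt = optimize.minimize_scalar(negll, bounds=(-18.0, 3.0), method="bounded", options={"xatol": 1e-3})
            alpha = float(np.exp(opt.x))
        else:
            alpha = float(dispersion)
        full = _glm_nb_fit(y, X, offset, alpha)
        red = _glm_nb_fit(y, Xr, offset, alpha)
        if not (full.converged and red.converged):
            res.fit_flag = "no_convergence"
            return res
    except Exception:
        res.fit_flag = "no_convergence"
        return res
    lrt = max(2.0 * (full.llf - red.llf), 0.0)
    coef = full.params[-1]
    se = full.bse[-1]
    res.estimate = coef / LN2
    res.se = se / LN2
    res.lrt = lrt
    res.p = float(stats.chi2.sf(lrt, df=1))
    res.z = res.estimate / res.se if se > 0 else np.nan
    res.extra["dispersion"] = alpha
    return res


# ---------------------------------------------------------------------------
# random-intercept linear mixed model trend test
# ---------------------------------------------------------------------------


def _factor_indicators(metadata: pd.DataFrame, factors) -> list[np.ndarray]:
    mats = []
    for f in factors:
        dummies = pd.get_dummies(metadata[f].astype("category"), dtype=float)
        if dummies.shape[1] < 2:
            raise ValueError(f"random factor {f!r} needs >=2 levels")
        mats.append(dummies.to_numpy())
    return mats


class _LMMProblem:
    """Cross-product representation of y = X beta + sum_k Z_k b_k + e.

    With U = [Z_1 | ... | Z_K] and per-block variance ratios gamma_k, the
    marginal covariance is sigma^2 * V, V = I + U diag(g) U'.  Every quantity
    the profiled ML log-likelihood needs — beta-hat, the generalized RSS and
    log|V| — reduces via the Woodbury identity to operations on q x q
    cross-products (q = total random-effect levels), precomputed once, so an
    evaluation costs O(q^3) instead of O(n^3).
    """

    def __init__(self, y, X, Z_list):
        self.n = y.shape[0]
        self.block_sizes = [Z.shape[1] for Z in Z_list]
        U = np.hstack(Z_list) if Z_list else np.zeros((self.n, 0))
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.UtX = U.T @ X
        self.Uty = U.T @ y
        self.UtU = U.T @ U

    def _expand(self, gammas):
        return np.concatenate([
            np.full(q, g) for q, g in zip(self.block_sizes, gammas)
        ]) if self.block_sizes else np.zeros(0)

    def profiled(self, gammas):
        """(loglik, beta, (X'V^-1X)^-1, sigma2_ML) at fixed variance ratios."""
        g = self._expand(np.maximum(np.asarray(gammas, dtype=float), 0.0))
        sq = np.sqrt(g)
        q = g.shape[0]
        if q:
            K = np.eye(q) + (sq[:, None] * self.UtU) * sq[None, :]
            c, low = cho_factor(K, lower=True)
            logdetV = 2.0 * np.sum(np.log(np.diag(c)))
            a = sq[:, None] * self.UtX
            b = sq * self.Uty
            Kia = cho_solve((c, low), a)
            Kib = cho_solve((c, low), b)
            XtViX = self.XtX - a.T @ Kia
            XtViy = self.Xty - a.T @ Kib
            ytViy = self.yty - b @ Kib
        else:
            logdetV = 0.0
            XtViX, XtViy, ytViy = self.XtX, self.Xty, self.yty
        beta = np.linalg.solve(XtViX, XtViy)
        rss = max(float(ytViy - XtViy @ beta), 1e-300)
        sigma2 = rss / self.n
        ll = -0.5 * (self.n * np.log(2.0 * np.pi * sigma2) + logdetV + self.n)
        return ll, beta, np.linalg.inv(XtViX), sigma2


def _fit_lmm_ml(y, X, Z_list):
    """Maximize the profiled ML log-likelihood over variance ratios >= 0."""
    prob = _LMMProblem(y, X, Z_list)
    k = len(Z_list)
    if k == 0:
        ll, beta, covu, s2 = prob.profiled([])
        return ll, beta, covu, s2, np.array([])

    def neg(g):
        return -prob.profiled(g)[0]

    best = None
    for start in ([0.1] * k, [1.0] * k):
        r = optimize.minimize(
            neg, np.asarray(start, dtype=float), method="L-BFGS-B",
            bounds=[(0.0, 1e4)] * k, options={"ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or r.fun < best.fun:
            best = r
    gam = np.maximum(best.x, 0.0)
    # the all-zero boundary is a legal optimum the line search can miss
    if neg([0.0] * k) < best.fun:
        gam = np.zeros(k)
    ll, beta, covu, s2 = prob.profiled(gam)
    return ll, beta, covu, s2, gam


def lmm_trend_lrt(
    abundance_row,
    metadata: pd.DataFrame,
    spec: ModelSpec = PROTEIN_SPEC,
    feature_id: str = "",
) -> TrendResult:
    """Likelihood-ratio trend test for one protein's (rank-normal) abundances.

    Full and reduced models share the random-intercept structure; each is fit
    by maximum likelihood, with the variance ratios of the random factors
    optimized directly on the profiled log-likelihood (the fixed effects and
    residual variance are profiled out in closed form by GLS).  ML rather
    than REML is used throughout so the two fixed-effect structures have
    comparable likelihoods.

    A variance ratio estimated at the zero boundary is a valid fit and is
    noted in ``fit_flag``.
    """
    y = np.asarray(abundance_row, dtype=float)
    if y.shape[0] != len(metadata):
        raise ValueError("abundance row and metadata are misaligned")
    X, Xr, _ = build_design(metadata, spec.focal, spec.covariates)
    Z = _factor_indicators(metadata, spec.random)
    res = TrendResult(feature_id=feature_id)
    try:
        ll_f, beta, covu, s2, gam_f = _fit_lmm_ml(y, X, Z)
        ll_r, *_ = _fit_lmm_ml(y, Xr, Z)
    except np.linalg.LinAlgError:
        res.fit_flag = "no_convergence"
        return res
    lrt = max(2.0 * (ll_f - ll_r), 0.0)
    res.estimate = float(beta[-1])
    res.se = float(np.sqrt(s2 * covu[-1, -1]))
    res.lrt = lrt
    res.p = float(stats.chi2.sf(lrt, df=1))
    res.z = res.estimate / res.se if res.se > 0 else np.nan
    res.extra["variance_ratios"] = dict(zip(spec.random, gam_f.tolist()))
    if any(g < 1e-8 for g in gam_f):
        res.fit_flag = "vc_boundary"
    return res


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------


def _check_p(p: np.ndarray) -> None:
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")


def holm_adjust(p) -> np.ndarray:
    """Holm step-down family-wise adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    _check_p(p)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    _check_p(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def attach_adjustments(table: pd.DataFrame) -> pd.DataFrame:
    """Add p_holm and q_bh columns; flagged (non-'ok'/'vc_boundary') rows are
    excluded from the multiple-testing family and get NaN adjustments."""
    table = table.copy()
    ok = table["fit_flag"].isin(["ok", "vc_boundary"]) & table["p"].notna()
    table["p_holm"] = np.nan
    table["q_bh"] = np.nan
    if ok.any():
        # stable order: sort by (p, feature_id) for reproducible ties
        sub = table.loc[ok].sort_values(["p", "feature_id"], kind="mergesort")
        table.loc[sub.index, "p_holm"] = holm_adjust(sub["p"].to_numpy())
        table.loc[sub.index, "q_bh"] = bh_adjust(sub["p"].to_numpy())
    return table


_RESULT_COLUMNS = ["feature_id", "estimate", "se", "lrt", "p", "p_holm", "q_bh", "z", "fit_flag"]


def _results_to_table(results: list[TrendResult]) -> pd.DataFrame:
    rows = [
        {
            "feature_id": r.feature_id, "estimate": r.estimate, "se": r.se,
            "lrt": r.lrt, "p": r.p, "z": r.z, "fit_flag": r.fit_flag,
        }
        for r in results
    ]
    table = pd.DataFrame(rows)
    return attach_adjustments(table)[_RESULT_COLUMNS]


def nb_trend_table(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    metadata: pd.DataFrame,
    spec: ModelSpec = MRNA_SPEC,
) -> pd.DataFrame:
    """Run :func:`nb_trend_lrt` over every row of a genes x samples count matrix."""
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    results = [
        nb_trend_lrt(counts.loc[g].to_numpy(dtype=float), sf, metadata, spec, feature_id=str(g))
        for g in counts.index
    ]
    return _results_to_table(results)


def lmm_trend_table(
    abundances: pd.DataFrame,
    metadata: pd.DataFrame,
    spec: ModelSpec = PROTEIN_SPEC,
) -> pd.DataFrame:
    """Run :func:`lmm_trend_lrt` over every row of a proteins x samples matrix."""
    results = [
        lmm_trend_lrt(abundances.loc[g].to_numpy(dtype=float), metadata, spec, feature_id=str(g))
        for g in abundances.index
    ]
    return _results_to_table(results)


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


def trend_power(n_per_group: int, effect_sd: float, alpha: float, n_groups: int = 3) -> float:
    """Normal-approximation power of the linear age-trend contrast.

    The trend strength ``effect_sd`` is the difference in means between the
    first and last age groups in units of the within-group SD.  With coded
    group values spanning one unit (e.g. -0.5, 0, 0.5), the slope equals
    ``effect_sd`` and its standard error is ``1/sqrt(n_per_group * sum(c^2))``
    in SD units, giving two-sided power
    ``Phi(ncp - z_{1-a/2}) + Phi(-ncp - z_{1-a/2})``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_per_group < 2:
        raise ValueError("need at least 2 per group")
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    c = np.linspace(-0.5, 0.5, n_groups)
    c = c - c.mean()
    ncp = abs(effect_sd) * np.sqrt(n_per_group * np.sum(c**2))
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(ncp - zcrit) + stats.norm.cdf(-ncp - zcrit))
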