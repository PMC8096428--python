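import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

import duotrend as dt
from duotrend.trendtest import (
    MRNA_SPEC,
    PROTEIN_SPEC,
    ModelSpec,
    _fit_lmm_ml,
    _LMMProblem,
    build_design,
)


def toy_metadata(n_per_cell=10, seed=0, n_tags=4, n_gens=3):
    rng = np.random.default_rng(seed)
    rows = []
    for age_code in (-0.5, 0.0, 0.5):
        for sex in ("F", "M"):
            for _ in range(n_per_cell):
                rows.append({"age_coded": age_code, "sex": sex})
    meta = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])
    n = len(meta)
    meta["batch"] = [f"B{b}" for b in rng.integers(0, 2, n)]
    meta["tag"] = [f"T{t}" for t in rng.integers(0, n_tags, n)]
    meta["generation"] = [f"G{g}" for g in rng.integers(0, n_gens, n)]
    return meta


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------


class TestAdjustments:
    def test_holm_hand_stepped_pair(self):
        assert np.allclose(dt.holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_holm_single_p_unchanged(self):
        assert dt.holm_adjust([0.3]) == pytest.approx([0.3])

    def test_bh_hand_stepped_triple(self):
        assert np.allclose(dt.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_bh_equal_ps_unchanged(self):
        assert np.allclose(dt.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_dominance_holm_above_raw_and_bh_below_holm(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 30))
            holm = dt.holm_adjust(p)
            bh = dt.bh_adjust(p)
            assert np.all(holm >= p - 1e-12)
            assert np.all(bh <= holm + 1e-12)

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            dt.holm_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            dt.bh_adjust([-0.1])


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


class TestPower:
    def test_planned_design_reaches_eighty_percent(self):
        # 64/group, 0.5 within-group-SD first-to-last difference, alpha 0.05
        assert dt.trend_power(64, 0.5, 0.05) == pytest.approx(0.80, abs=0.01)

    def test_null_effect_power_equals_alpha(self):
        assert dt.trend_power(50, 0.0, 0.05) == pytest.approx(0.05, abs=1e-12)

    def test_monotone_in_n_and_effect(self):
        powers_n = [dt.trend_power(n, 0.4, 0.05) for n in (10, 30, 90)]
        powers_e = [dt.trend_power(40, e, 0.05) for e in (0.2, 0.4, 0.8)]
        assert powers_n == sorted(powers_n) and powers_e == sorted(powers_e)

    def test_invalid_alpha_raises(self):
        with pytest.raises(ValueError):
            dt.trend_power(10, 0.5, 1.5)


# ---------------------------------------------------------------------------
# NB GLM trend test
# ---------------------------------------------------------------------------


def poisson_irls_loglik(y, X, offset, tol=1e-12, maxiter=200):
    """Independent iteratively-reweighted least-squares Poisson fit."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean() + 0.5) - offset.mean()
    for _ in range(maxiter):
        eta = X @ beta + offset
        mu = np.exp(eta)
        W = mu
        z = eta - offset + (y - mu) / mu
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    mu = np.exp(X @ beta + offset)
    from scipy.special import gammaln
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


class TestNBTrend:
    def test_constant_counts_give_null_result(self):
        meta = toy_metadata()
        y = np.full(len(meta), 17.0)
        res = dt.nb_trend_lrt(y, np.ones(len(meta)), meta, MRNA_SPEC)
        assert res.fit_flag == "ok"
        assert res.lrt == pytest.approx(0.0, abs=1e-4)
        assert res.p > 0.99

    def test_all_zero_row_is_flagged_not_raised(self):
        meta = toy_metadata()
        res = dt.nb_trend_lrt(np.zeros(len(meta)), np.ones(len(meta)), meta)
        assert res.fit_flag == "all_zero"
        assert np.isnan(res.p)

    def test_zero_dispersion_limit_matches_independent_poisson_irls(self, rng):
        # with alpha pinned near zero the NB LRT must agree with a Poisson
        # GLM LRT computed by a from-scratch IRLS implementation
        meta = toy_metadata(n_per_cell=8, seed=3)
        n = len(meta)
        sf = np.exp(rng.normal(0, 0.2, n))
        age = meta["age_coded"].to_numpy()
        y = rng.poisson(np.exp(3.0 + 0.4 * age) * sf).astype(float)
        res = dt.nb_trend_lrt(y, sf, meta, MRNA_SPEC, dispersion=1e-8)
        X, Xr, _ = build_design(meta, MRNA_SPEC.focal, MRNA_SPEC.covariates)
        off = np.log(sf)
        lrt_oracle = 2.0 * (poisson_irls_loglik(y, X, off) - poisson_irls_loglik(y, Xr, off))
        assert res.lrt == pytest.approx(lrt_oracle, abs=1e-4)

    def test_recovers_simulated_log2_slope(self, rng):
        meta = toy_metadata(n_per_cell=30, seed=4)
        age = meta["age_coded"].to_numpy()
        slope_ln = 0.6
        mu = np.exp(5.0 + slope_ln * age)
        y = rng.poisson(rng.gamma(10.0, mu / 10.0)).astype(float)
        res = dt.nb_trend_lrt(y, np.ones(len(meta)), meta)
        assert res.estimate == pytest.approx(slope_ln / np.log(2), abs=0.25)
        assert res.p < 1e-4

    def test_estimate_se_ratio_equals_z(self, trend_tables):
        mrna_tab, _ = trend_tables
        ok = mrna_tab[mrna_tab.fit_flag == "ok"]
        assert np.allclose(ok["z"], ok["estimate"] / ok["se"])


# ---------------------------------------------------------------------------
# LMM trend test
# ---------------------------------------------------------------------------


def dense_profiled_loglik(y, X, Z_list, gammas):
    """Closed-form GLS evaluation of the profiled ML log-likelihood with an
    explicitly assembled marginal covariance (the brute-force oracle)."""
    n = y.shape[0]
    V = np.eye(n)
    for g, Z in zip(gammas, Z_list):
        V += g * Z @ Z.T
    c = cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(c[0])))
    ViX = cho_solve(c, X)
    beta = np.linalg.solve(X.T @ ViX, X.T @ cho_solve(c, y))
    r = y - X @ beta
    rss = float(r @ cho_solve(c, r))
    s2 = rss / n
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdetV + n)


class TestLMMTrend:
    def test_zero_variance_limit_equals_ols_nested_lrt(self, rng):
        meta = toy_metadata(n_per_cell=6, seed=5)
        n = len(meta)
        y = rng.normal(size=n)
        X, Xr, _ = build_design(meta, "age_coded", ("sex",))
        prob_f, prob_r = _LMMProblem(y, X, []), _LMMProblem(y, Xr, [])
        ll_f = prob_f.profiled([])[0]
        ll_r = prob_r.profiled([])[0]
        # OLS nested-model LRT: n * log(RSS_r / RSS_f)
        rss = lambda Xd: np.sum((y - Xd @ np.linalg.lstsq(Xd, y, rcond=None)[0]) ** 2)
        lrt_ols = n * np.log(rss(Xr) / rss(X))
        assert 2 * (ll_f - ll_r) == pytest.approx(lrt_ols, abs=1e-6)

    def test_profiled_loglik_matches_grid_gls_oracle(self, rng):
        # 1 random factor with 4 groups, n=24, fixed variance-ratio values
        rng_local = np.random.default_rng(7)
        n = 24
        groups = np.repeat(np.arange(4), 6)
        Z = np.eye(4)[groups]
        X = np.column_stack([np.ones(n), rng_local.normal(size=n)])
        y = (X @ [1.0, 0.5] + Z @ rng_local.normal(0, 0.8, 4)
             + rng_local.normal(0, 1.0, n))
        prob = _LMMProblem(y, X, [Z])
        grid = np.concatenate([[0.0], np.geomspace(1e-3, 50, 40)])
        for g in grid[::7]:
            assert prob.profiled([g])[0] == pytest.approx(
                dense_profiled_loglik(y, X, [Z], [g]), abs=1e-4
            )
        # and the optimizer attains at least the best grid value
        ll_opt = _fit_lmm_ml(y, X, [Z])[0]
        ll_grid = max(dense_profiled_loglik(y, X, [Z], [g]) for g in grid)
        assert ll_opt >= ll_grid - 1e-4

    def test_detects_planted_trend_and_ignores_null(self, rng):
        meta = toy_metadata(n_per_cell=12, seed=9)
        n = len(meta)
        tag_eff = {t: rng.normal(0, 0.5) for t in meta["tag"].unique()}
        base = meta["tag"].map(tag_eff).to_numpy() + rng.normal(0, 1, n)
        res_null = dt.lmm_trend_lrt(dt.rank_normal_transform(base), meta)
        y = base + 1.2 * meta["age_coded"].to_numpy()
        res_sig = dt.lmm_trend_lrt(dt.rank_normal_transform(y), meta)
        assert res_sig.p < 1e-3
        assert res_sig.estimate > 0
        assert res_null.p > 0.01

    def test_sex_focal_reuses_the_machinery(self, rng):
        meta = toy_metadata(n_per_cell=12, seed=11)
        n = len(meta)
        y = 1.0 * (meta["sex"] == "M").to_numpy(float) + rng.normal(0, 1, n)
        spec_sex = PROTEIN_SPEC.with_focal("sex")
        assert spec_sex.focal == "sex" and "age_coded" in spec_sex.covariates
        res = dt.lmm_trend_lrt(dt.rank_normal_transform(y), meta, spec_sex)
        assert res.p < 1e-3

    def test_singular_design_raises_with_column_names(self):
        meta = toy_metadata(n_per_cell=4)
        meta["dup"] = meta["age_coded"]
        spec = ModelSpec(focal="age_coded", covariates=("sex", "dup"), random=("tag",))
        with pytest.raises(ValueError, match="singular"):
            dt.lmm_trend_lrt(np.zeros(len(meta)), meta, spec)

    def test_boundary_variance_is_flagged_not_failed(self, rng):
        meta = toy_metadata(n_per_cell=8, seed=13)
        y = rng.normal(size=len(meta))  # no group structure at all
        res = dt.lmm_trend_lrt(y, meta, PROTEIN_SPEC)
        assert res.fit_flag in ("ok", "vc_boundary")
        assert np.isfinite(res.p)

    def test_full_loglik_dominates_reduced(self, trend_tables):
        _, prot_tab = trend_tables
        ok = prot_tab[prot_tab["lrt"].notna()]
        assert np.all(ok["lrt"] >= 0.0)


class TestModelSpec:
    def test_focal_duplicated_in_covariates_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(focal="age_coded", covariates=("age_coded",))
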