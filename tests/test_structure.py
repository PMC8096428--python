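import itertools

import numpy as np
import pandas as pd
import pytest

import duotrend as dt
from tests.conftest import small_cohort_config


class TestPCA:
    def test_rank_one_matrix_concentrates_all_variance_in_pc1(self, rng):
        row = rng.normal(size=30)
        m = pd.DataFrame(np.outer([1.0, 2.0, -0.5, 3.0], row))
        res = dt.pca_variance(m, k=2)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_two_independent_features_split_variance(self, rng):
        m = pd.DataFrame(rng.normal(size=(2, 4000)))
        res = dt.pca_variance(m, k=2)
        assert res.variance_fraction[0] == pytest.approx(0.5, abs=0.05)

    def test_fractions_match_covariance_eigenvalues(self, rng):
        m = pd.DataFrame(rng.normal(size=(12, 40)))
        res = dt.pca_variance(m, k=5)
        X = m.to_numpy().T
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        assert np.allclose(res.variance_fraction, evals / evals.sum(), atol=1e-8)

    def test_fraction_invariants(self, rng):
        m = pd.DataFrame(rng.normal(size=(15, 25)))
        res = dt.pca_variance(m, k=3)
        f = res.variance_fraction
        assert np.all(np.diff(f) <= 1e-12)
        assert f.sum() <= 1 + 1e-8

    def test_feature_reordering_leaves_scores_invariant(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 20)),
                         index=[f"g{i}" for i in range(10)])
        res1 = dt.pca_variance(m, k=3)
        perm = rng.permutation(10)
        res2 = dt.pca_variance(m.iloc[perm], k=3)
        assert np.allclose(res1.scores.to_numpy(), res2.scores.to_numpy(), atol=1e-8)

    def test_k_out_of_range_raises(self, rng):
        m = pd.DataFrame(rng.normal(size=(3, 5)))
        with pytest.raises(ValueError):
            dt.pca_variance(m, k=10)


class TestPCAssociation:
    def test_exact_sex_indicator_is_overwhelming(self, rng):
        sex = np.array(["F", "M"] * 50)
        score = (sex == "M").astype(float)
        assert dt.pc_association(score, sex) < 1e-15

    def test_exact_age_score(self, rng):
        age = np.repeat([-0.5, 0.0, 0.5], 30)
        sex = np.array(["F", "M"] * 45)
        assert dt.pc_association(age, age) < 1e-15
        assert dt.pc_association(age.astype(float), sex) > 0.01

    def test_null_scores_give_uniform_p(self, rng):
        from scipy import stats
        age = np.repeat([-0.5, 0.0, 0.5], 40)
        ps = [dt.pc_association(rng.normal(size=120), age) for _ in range(300)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError):
            dt.pc_association(np.arange(10.0), np.ones(10))


class TestMarkers:
    def test_recovers_planted_markers(self):
        profiles, truth = dt.simulate_reference_profiles(4, 300, 20, seed=9)
        found = dt.select_markers(profiles, max_markers=50, min_ratio=2.0)
        for t, genes in truth.items():
            recovered = len(set(genes) & set(found.get(t, []))) / len(genes)
            assert recovered >= 0.9

    def test_max_marker_cap_is_respected(self):
        profiles, _ = dt.simulate_reference_profiles(3, 400, 60, seed=10)
        found = dt.select_markers(profiles, max_markers=50)
        assert all(len(v) <= 50 for v in found.values())

    def test_identical_types_yield_no_discriminating_markers(self, rng):
        col = rng.uniform(1, 5, 50)
        profiles = pd.DataFrame({"t1": col, "t2": col})
        found = dt.select_markers(profiles, min_ratio=2.0)
        assert found == {}

    def test_single_type_reference_rejected(self, rng):
        with pytest.raises(ValueError):
            dt.select_markers(pd.DataFrame({"t1": rng.uniform(1, 5, 10)}))


class TestSPV:
    def test_two_identical_markers_reduce_to_standardized_profile(self, rng):
        sig = rng.normal(size=25)
        bulk = pd.DataFrame([sig, sig], index=["m1", "m2"],
                            columns=[f"s{i}" for i in range(25)])
        res = dt.compute_spv(bulk, {"ct": ["m1", "m2"]}, "ct")
        z = (sig - sig.mean()) / sig.std()
        assert np.allclose(res["spv"].to_numpy(), z, atol=1e-8)

    def test_sample_permutation_equivariance(self, rng):
        bulk = pd.DataFrame(rng.normal(size=(6, 30)),
                            index=[f"m{i}" for i in range(6)],
                            columns=[f"s{i}" for i in range(30)])
        markers = {"ct": [f"m{i}" for i in range(6)]}
        res = dt.compute_spv(bulk, markers, "ct")
        perm = rng.permutation(30)
        res_p = dt.compute_spv(bulk.iloc[:, perm], markers, "ct")
        assert np.allclose(res_p["spv"].to_numpy(), res["spv"].to_numpy()[perm], atol=1e-8)

    def test_fewer_than_two_markers_raises(self, rng):
        bulk = pd.DataFrame(rng.normal(size=(3, 10)), index=["a", "b", "c"])
        with pytest.raises(ValueError):
            dt.compute_spv(bulk, {"ct": ["a"]}, "ct")

    def test_mixture_recovery_and_age_trend_detection(self):
        # B-cell-like type whose proportion increases with age must be
        # recovered by its SPV and flagged by the trend test
        _, _, meta, _ = dt.simulate_cohort(small_cohort_config(seed=77))
        # marker genes kept to a small fraction of the universe so the
        # upper-quartile normalization is insensitive to composition shifts
        profiles, _ = dt.simulate_reference_profiles(4, 1500, 25, seed=78)
        rng = np.random.default_rng(79)
        n = len(meta)
        raw = np.abs(rng.normal(1.0, 0.1, (4, n)))
        raw[0] = 0.4 + 0.3 * meta["age_coded"].to_numpy() + rng.normal(0, 0.03, n)
        props = raw / raw.sum(axis=0)
        props_df = pd.DataFrame(props, index=profiles.columns, columns=meta.index)
        bulk = dt.simulate_bulk_mixture(profiles, props_df, noise_log_sd=0.15, seed=80)
        markers = dt.select_markers(profiles)
        table = dt.spv_table(dt.upper_quartile_normalize(bulk), markers, meta)
        row = table[table["cell_type"] == "type0"].iloc[0]
        spv = row[meta.index].to_numpy(dtype=float)
        assert abs(np.corrcoef(spv, props[0])[0, 1]) > 0.9
        assert row["trend_p"] < 0.05

    def test_constant_proportions_show_no_age_trend(self):
        _, _, meta, _ = dt.simulate_cohort(small_cohort_config(seed=81))
        profiles, _ = dt.simulate_reference_profiles(3, 1200, 20, seed=82)
        rng = np.random.default_rng(83)
        raw = np.abs(rng.normal(1.0, 0.1, (3, len(meta))))
        props = raw / raw.sum(axis=0)
        props_df = pd.DataFrame(props, index=profiles.columns, columns=meta.index)
        bulk = dt.simulate_bulk_mixture(profiles, props_df, noise_log_sd=0.15, seed=84)
        table = dt.spv_table(dt.upper_quartile_normalize(bulk),
                             dt.select_markers(profiles), meta)
        assert (table["trend_p"] > 0.01).all()


class TestORA:
    @staticmethod
    def enumeration_oracle(universe_size, category_size, selected_size, overlap):
        """Exact tail probability by enumerating all selections."""
        universe = list(range(universe_size))
        category = set(range(category_size))
        total = hits = 0
        for sel in itertools.combinations(universe, selected_size):
            total += 1
            if len(category & set(sel)) >= overlap:
                hits += 1
        return hits / total

    @pytest.mark.parametrize("M,K,N,k", [(10, 5, 4, 4), (12, 6, 5, 3), (8, 3, 4, 1)])
    def test_matches_exact_enumeration(self, M, K, N, k):
        universe = [f"g{i}" for i in range(M)]
        category = universe[:K]
        selected = universe[:k] + universe[K:K + (N - k)]
        overlap, p = dt.ora_hypergeometric(selected, category, universe)
        assert overlap == k
        assert p == pytest.approx(self.enumeration_oracle(M, K, N, k), abs=1e-12)

    def test_category_equals_universe_is_certain(self):
        u = [f"g{i}" for i in range(6)]
        _, p = dt.ora_hypergeometric(u[:3], u, u)
        assert p == pytest.approx(1.0)

    def test_zero_overlap_has_p_one(self):
        u = [f"g{i}" for i in range(10)]
        overlap, p = dt.ora_hypergeometric(u[:3], u[5:], u)
        assert overlap == 0 and p == pytest.approx(1.0)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            dt.ora_hypergeometric(["a"], ["a"], [])
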