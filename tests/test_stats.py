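"""Robust inference against brute-force matrix and step-up oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fcbag import stats
from fcbag.synthetic import SyntheticConfig, generate_cohort


def _hc3_oracle(y, x):
    """Direct evaluation of the HC3 sandwich covariance."""
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    e = y - x @ beta
    h = np.diag(x @ xtx_inv @ x.T)
    omega = np.diag((e / (1 - h)) ** 2)
    cov = xtx_inv @ x.T @ omega @ x @ xtx_inv
    return beta, cov


def _bh_oracle(p):
    """Step-up arithmetic: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestResidualizeBag:
    def test_zscore_postconditions(self, rng):
        n = 200
        out = stats.residualize_bag(rng.normal(2, 5, n), rng.integers(0, 2, n),
                                    rng.uniform(0.05, 0.3, n), rng.uniform(20, 70, n))
        assert out["bag_z"].mean() == pytest.approx(0.0, abs=1e-8)
        assert out["bag_z"].std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_covariate_independent_bag_nearly_unchanged(self, rng):
        n = 300
        bag = rng.normal(0, 5, n)
        out = stats.residualize_bag(bag, rng.integers(0, 2, n),
                                    rng.uniform(0.05, 0.3, n), rng.uniform(20, 70, n))
        direct = (bag - bag.mean()) / bag.std(ddof=1)
        assert np.corrcoef(out["bag_z"], direct)[0, 1] > 0.98

    def test_fully_explained_bag_rejected(self, rng):
        n = 50
        age = rng.uniform(20, 70, n)
        with pytest.raises(ValueError, match="zero-variance"):
            stats.residualize_bag(3 * age**2, rng.integers(0, 2, n),
                                  rng.uniform(0.05, 0.3, n), age)


class TestHC3:
    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(12, 30), rng.integers(2, 5)
        x = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        y = rng.standard_normal(n)
        res = stats.hc3_inference(y, x)
        beta, cov = _hc3_oracle(y, x)
        np.testing.assert_allclose(res["beta"], beta, atol=1e-8)
        np.testing.assert_allclose(res["se_hc3"], np.sqrt(np.diag(cov)), atol=1e-8)

    def test_matches_statsmodels_hc3(self, rng):
        import statsmodels.api as sm
        x = np.column_stack([np.ones(40), rng.standard_normal((40, 2))])
        y = x @ np.array([1.0, 0.5, -0.3]) + rng.standard_normal(40) * (1 + np.abs(x[:, 1]))
        res = stats.hc3_inference(y, x)
        fit = sm.OLS(y, x).fit(cov_type="HC3")
        np.testing.assert_allclose(res["beta"], fit.params, atol=1e-10)
        np.testing.assert_allclose(res["se_hc3"], fit.bse, atol=1e-10)

    def test_homoskedastic_balanced_close_to_classical(self, rng):
        g = np.repeat([0.0, 1.0], 20)
        y = 2 + 0.5 * g + rng.standard_normal(40)
        x = np.column_stack([np.ones(40), g])
        res = stats.hc3_inference(y, x)
        e = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        s2 = e @ e / (40 - 2)
        se_classical = np.sqrt(s2 * np.diag(np.linalg.inv(x.T @ x)))
        assert np.all(np.abs(res["se_hc3"] - se_classical) / se_classical < 0.15)

    def test_exact_fit_degenerate_path(self):
        x = np.column_stack([np.ones(6), np.arange(6.0)])
        y = 2 + 3 * np.arange(6.0)
        with pytest.warns(UserWarning, match="exact fit"):
            res = stats.hc3_inference(y, x)
        assert np.allclose(res["se_hc3"], 0.0, atol=1e-10)

    def test_unit_leverage_rejected(self):
        x = np.column_stack([np.ones(5), np.array([0, 0, 0, 0, 100.0])])
        y = np.array([1.0, 2.0, 1.5, 1.2, 50.0])
        with pytest.raises(ValueError, match="leverage"):
            stats.hc3_inference(y, x)


class TestGroupGLM:
    @staticmethod
    def _df(n=400, shift=0.6, seed=0):
        rng = np.random.default_rng(seed)
        dx = (rng.uniform(size=n) < 0.5).astype(int)
        df = pd.DataFrame({
            "diagnosis": dx,
            "sex": rng.integers(0, 2, n),
            "age": rng.uniform(20, 70, n),
            "mean_fd": rng.uniform(0.05, 0.3, n),
            "site": rng.choice(["site00", "site01"], n),
        })
        df["bag_z"] = shift * dx + rng.standard_normal(n)
        return df

    def test_injected_shift_recovered(self):
        res = stats.group_difference_glm(self._df(shift=0.6, seed=1))
        assert 0.4 <= res.beta <= 0.8
        assert res.ci_low > 0

    def test_null_coverage(self):
        covered = 0
        for seed in range(50):
            res = stats.group_difference_glm(self._df(n=150, shift=0.0, seed=seed))
            covered += res.ci_low <= 0 <= res.ci_high
        assert covered >= 45

    def test_duplicating_rows_keeps_beta_shrinks_se(self):
        df = self._df(seed=2)
        res1 = stats.group_difference_glm(df)
        res2 = stats.group_difference_glm(pd.concat([df, df], ignore_index=True))
        assert res2.beta == pytest.approx(res1.beta, abs=1e-10)
        assert res2.se_hc3 < res1.se_hc3

    def test_single_group_site_warns(self):
        df = self._df(seed=3)
        df.loc[df["site"] == "site01", "diagnosis"] = 1
        with pytest.warns(UserWarning, match="single diagnosis"):
            stats.group_difference_glm(df)


class TestWelch:
    def test_equal_means_zero_statistics(self, rng):
        x = rng.standard_normal(30)
        c = stats.welch_contrast(x, x.copy())
        assert c.welch_t == pytest.approx(0.0, abs=1e-12)
        assert c.cohens_d == pytest.approx(0.0, abs=1e-12)

    def test_textbook_fixture_matches_satterthwaite_arithmetic(self):
        x1 = np.array([19.8, 20.4, 19.6, 17.8, 18.5, 18.9, 18.3, 18.9, 19.5, 22.0])
        x2 = np.array([28.2, 26.6, 20.1, 23.3, 25.2, 22.1, 17.7, 27.6, 20.6, 13.7])
        c = stats.welch_contrast(x1, x2)
        v1, v2, n1, n2 = x1.var(ddof=1), x2.var(ddof=1), 10, 10
        t_hand = (x2.mean() - x1.mean()) / np.sqrt(v1 / n1 + v2 / n2)
        df_hand = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        assert c.welch_t == pytest.approx(t_hand, abs=1e-10)
        assert c.welch_df == pytest.approx(df_hand, abs=1e-10)
        assert c.p == pytest.approx(2 * sps.t.sf(abs(t_hand), df_hand), abs=1e-10)

    def test_hedges_correction_shrinks_and_vanishes(self, rng):
        base = rng.standard_normal(200) + 0.5
        ref = rng.standard_normal(200)
        ratios = []
        for n in (5, 20, 200):
            c = stats.welch_contrast(ref[:n], base[:n])
            assert abs(c.hedges_g) < abs(c.cohens_d)
            ratios.append(c.hedges_g / c.cohens_d)
        assert ratios[-1] > ratios[0] and ratios[-1] > 0.995

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            stats.welch_contrast(np.ones(5), np.array([1.0, 2.0, 3.0]))

    def test_per_site_welch_uses_within_site_scores(self, rng):
        n = 200
        df = pd.DataFrame({
            "site": np.repeat(["a", "b"], n // 2),
            "diagnosis": np.tile([0, 1], n // 2),
            "bag_resid": rng.standard_normal(n),
        })
        df.loc[df["site"] == "b", "bag_resid"] += 100  # site offset must not matter
        out = stats.per_site_welch(df)
        assert set(out["site"]) == {"a", "b"}
        assert np.all(np.abs(out["welch_t"]) < 3)


class TestRankINT:
    def test_three_value_example(self):
        """[5,1,9] -> ranks [2,1,3] -> p [.5,.25,.75] -> z [0, -0.6745, +0.6745]."""
        v = np.array([5.0, 1.0, 9.0])
        ranks = sps.rankdata(v)
        p = ranks / 4
        z = np.sqrt(2) * sps.norm.ppf(p) / np.sqrt(2)  # erfinv identity
        np.testing.assert_allclose(z, [0.0, -0.67448975, 0.67448975], atol=1e-6)
        out = stats.rank_int(v)
        np.testing.assert_allclose(out, z / z.std(ddof=1), atol=1e-10)

    def test_matches_normal_quantile_oracle(self, rng):
        for seed in range(100):
            v = np.random.default_rng(seed).standard_normal(25)
            out = stats.rank_int(v)
            z = sps.norm.ppf(sps.rankdata(v) / 26)
            np.testing.assert_allclose(out, z / z.std(ddof=1), atol=1e-8)

    def test_symmetric_and_median_zero_for_odd_n(self):
        out = stats.rank_int(np.array([10.0, 20.0, 30.0, 40.0, 50.0]))
        np.testing.assert_allclose(out, -out[::-1], atol=1e-12)
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        v = rng.uniform(1, 10, 40)
        np.testing.assert_allclose(stats.rank_int(v), stats.rank_int(np.exp(v)), atol=1e-12)

    def test_spearman_one_and_unit_sd(self, rng):
        v = rng.standard_normal(60)
        out = stats.rank_int(v)
        assert sps.spearmanr(v, out).statistic == pytest.approx(1.0)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_missing_preserved_and_degenerate_rejected(self):
        v = np.array([1.0, np.nan, 3.0, 2.0])
        out = stats.rank_int(v)
        assert np.isnan(out[1]) and not np.isnan(out[[0, 2, 3]]).any()
        with pytest.raises(ValueError):
            stats.rank_int(np.array([2.0, 2.0, 2.0]))


class TestClinicalAssociation:
    @staticmethod
    def _truth_tables(loading, n=300, seed=0):
        cfg = SyntheticConfig(n_subjects=n, n_regions=6, n_timepoints=40,
                              case_fraction=1.0, clinical_loading=loading, seed=seed)
        c = generate_cohort(cfg)
        bag = c.truth["subjects"]["true_bag"].to_numpy()
        bag_z = (bag - bag.mean()) / bag.std(ddof=1)
        meta = c.metadata
        age_c = meta["age"] - meta["age"].mean()
        cov = pd.DataFrame({
            "sex": meta["sex"].astype(float), "age_c": age_c, "age_c2": age_c**2,
            "fd_c": meta["mean_fd"] - meta["mean_fd"].mean(),
        })
        return bag_z, meta, cov

    def test_loading_recovered_with_sign(self):
        bag_z, meta, cov = self._truth_tables(0.4, seed=1)
        z = stats.rank_int(meta["nss_total"].to_numpy(float))
        res = stats.clinical_association(bag_z, z, cov, meta["site"], predictor="nss_total")
        assert -0.6 <= res.beta <= -0.2
        assert res.ci_high < 0

    def test_null_loading_coverage(self):
        covered = 0
        for seed in range(50):
            bag_z, meta, cov = self._truth_tables(0.0, n=120, seed=seed)
            z = stats.rank_int(meta["nss_total"].to_numpy(float))
            res = stats.clinical_association(bag_z, z, cov, meta["site"])
            covered += res.ci_low <= 0 <= res.ci_high
        assert covered >= 45

    def test_self_association_degenerate(self, rng):
        bag_z, meta, cov = self._truth_tables(0.4, seed=2)
        with pytest.warns(UserWarning, match="exact fit"):
            res = stats.clinical_association(bag_z, bag_z.copy(), cov, meta["site"])
        assert res.beta == pytest.approx(1.0, abs=1e-8)

    def test_too_few_complete_cases_skipped(self, rng):
        bag_z, meta, cov = self._truth_tables(0.4, seed=3)
        z = np.full(len(bag_z), np.nan)
        z[:5] = rng.standard_normal(5)
        with pytest.warns(UserWarning, match="fewer than 10"):
            assert stats.clinical_association(bag_z, z, cov, meta["site"]) is None


class TestLongitudinal:
    @staticmethod
    def _visits(n=300, coupling=0.5, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        delta_bag = rng.normal(0, 5, n)
        nss_base = rng.normal(14, 7, n)
        eps = rng.standard_normal(n)
        zd = (delta_bag - delta_bag.mean()) / delta_bag.std(ddof=1)
        delta_nss = -coupling * zd + np.sqrt(1 - coupling**2) * eps
        base = pd.DataFrame({"subject_id": ids, "bag": rng.normal(0, 5, n),
                             "nss_total": nss_base})
        fu = pd.DataFrame({"subject_id": ids, "bag": base["bag"] - delta_bag,
                           "nss_total": nss_base - 3 * delta_nss})
        return base, fu

    def test_identical_visits_zero_delta(self):
        base, _ = self._visits()
        out = stats.longitudinal_delta(base, base.copy(), ["nss_total"])
        assert np.allclose(out["delta_bag"], 0)
        assert np.allclose(out["delta_nss_total"], 0)

    def test_coupled_change_negative_beta(self):
        base, fu = self._visits(coupling=0.5, seed=4)
        deltas = stats.longitudinal_delta(base, fu, ["nss_total"])
        table = stats.delta_associations(deltas, ["nss_total"])
        row = table.iloc[0]
        assert row["beta"] < 0 and row["ci_high"] < 0

    def test_duplicate_ids_rejected(self):
        base, fu = self._visits(n=20)
        bad = pd.concat([base, base.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicated"):
            stats.longitudinal_delta(bad, fu, ["nss_total"])


class TestFDR:
    def test_hand_worked_example(self):
        q = stats.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_and_tied_pvalues(self):
        assert stats.bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)
        np.testing.assert_allclose(stats.bh_fdr(np.full(5, 0.2)), 0.2, atol=1e-12)

    def test_all_permutations_of_six_match_step_up_oracle(self):
        base = np.array([0.001, 0.011, 0.039, 0.041, 0.27, 0.9])
        for perm in itertools.permutations(range(6)):
            p = base[list(perm)]
            np.testing.assert_allclose(stats.bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_families_corrected_separately(self):
        p = np.array([0.01, 0.04, 0.01, 0.04])
        fam = np.array([0, 0, 1, 1])
        q = stats.bh_fdr(p, fam)
        np.testing.assert_allclose(q[:2], _bh_oracle(p[:2]), atol=1e-12)
        np.testing.assert_allclose(q[2:], _bh_oracle(p[2:]), atol=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_fdr(np.array([0.1, np.nan]))


class TestPosthoc:
    def test_symmetric_bag_near_equal_groups(self, rng):
        bag_z = rng.standard_normal(2000)
        clin = pd.DataFrame({"nss_total": rng.standard_normal(2000)})
        out = stats.posthoc_extreme_groups(bag_z, clin, ["nss_total"])
        row = out.iloc[0]
        assert abs(row["n_younger"] - row["n_older"]) < 0.2 * row["n_younger"]

    def test_negative_loading_younger_group_scores_higher(self):
        cfg = SyntheticConfig(n_subjects=500, n_regions=6, n_timepoints=40,
                              case_fraction=1.0, clinical_loading=0.5, seed=6)
        c = generate_cohort(cfg)
        bag = c.truth["subjects"]["true_bag"].to_numpy()
        bag_z = (bag - bag.mean()) / bag.std(ddof=1)
        out = stats.posthoc_extreme_groups(bag_z, c.metadata, ["nss_total", "doi"])
        assert (out["mean_younger"] > out["mean_older"]).all()
        assert (out["p"] < 0.05).all()

    def test_infinite_threshold_skips_inference(self, rng):
        bag_z = rng.standard_normal(50)
        clin = pd.DataFrame({"nss_total": rng.standard_normal(50)})
        with pytest.warns(UserWarning, match="< 3"):
            out = stats.posthoc_extreme_groups(bag_z, clin, ["nss_total"],
                                               threshold=np.inf)
        assert np.isnan(out.iloc[0]["p"])
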