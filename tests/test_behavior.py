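"""Endpoint statistics against independent oracles and their published arithmetic."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mednf import behavior as bh
from mednf.synthetic import CohortConfig, simulate_cohort


def _reference_bh_stepup(p):
    """Independent Benjamini-Hochberg step-up (textbook formulation)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


class TestBhFdr:
    def test_published_five_test_adjustment(self):
        """The five behavioural p-values adjust to 0.005 for 0.001 and 0.041
        for each of 0.019/0.025/0.033."""
        raw = [0.019, 0.025, 0.033, 0.001, 0.50]
        adj = bh.bh_fdr(raw, bh.MultipleTestingConfig(m=5))
        assert np.round(adj, 3).tolist() == [0.041, 0.041, 0.041, 0.005, 0.500]
        np.testing.assert_allclose(adj, [0.04125, 0.04125, 0.04125, 0.005, 0.50])

    def test_single_p_identity(self):
        assert bh.bh_fdr([0.05], bh.MultipleTestingConfig(m=1))[0] == pytest.approx(0.05)

    def test_matches_independent_stepup_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 12))
            np.testing.assert_allclose(bh.bh_fdr(p), _reference_bh_stepup(p),
                                       atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10),
           st.randoms(use_true_random=False))
    @settings(max_examples=100, derandomize=True)
    def test_permutation_equivariance_and_idempotence(self, p, rnd):
        p = np.asarray(p)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adj = bh.bh_fdr(p)
        adj_perm = bh.bh_fdr(p[perm])
        np.testing.assert_allclose(adj[perm], adj_perm, atol=1e-12)
        # re-application never lowers values and preserves their ranking
        # (full idempotence does not hold for the step-up adjustment)
        re_adj = bh.bh_fdr(adj)
        assert (re_adj >= adj - 1e-12).all()
        order = np.argsort(adj, kind="stable")
        assert (np.diff(re_adj[order]) >= -1e-12).all()

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.random(8)
        adj = bh.bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            bh.bh_fdr([0.5, 1.5])


class TestPartialCorrelation:
    def test_published_p_values(self):
        """r = 0.53 at df = 28 gives two-sided p = 0.003 (3 dp); r = 0.71 at
        df = 12 gives p < 0.01."""
        assert round(bh.partial_correlation_from_r(0.53, 28).raw_p, 3) == 0.003
        res = bh.partial_correlation_from_r(0.71, 12)
        assert res.raw_p < 0.01
        assert res.raw_p == pytest.approx(0.0044, abs=5e-4)

    def test_no_covariates_equals_plain_pearson(self, rng):
        x, y = rng.normal(size=(2, 40))
        mine = bh.partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert mine.effect_size == pytest.approx(r_ref, abs=1e-12)
        assert mine.raw_p == pytest.approx(p_ref, rel=1e-9)

    def test_matches_two_stage_regression_oracle(self, rng):
        n = 50
        z = rng.normal(size=(n, 2))
        x = z @ [0.5, -0.3] + rng.normal(size=n)
        y = z @ [-0.2, 0.4] + 0.4 * x + rng.normal(size=n)
        mine = bh.partial_correlation(x, y, z)
        # independent two-stage oracle via explicit hat-matrix residuals
        Z1 = np.column_stack([np.ones(n), z])
        H = Z1 @ np.linalg.inv(Z1.T @ Z1) @ Z1.T
        rx, ry = x - H @ x, y - H @ y
        r_oracle = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
        assert mine.effect_size == pytest.approx(r_oracle, abs=1e-10)
        assert mine.df == n - 2 - 2

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 36
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["x", "y", "a", "b"])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"])
        mine = bh.partial_correlation(df.x, df.y, df[["a", "b"]].to_numpy())
        assert mine.effect_size == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert mine.raw_p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_insufficient_df_raises(self):
        with pytest.raises(ValueError, match="df|observations"):
            bh.partial_correlation([1, 2, 3], [3, 2, 1], np.ones((3, 1)) * [[1], [2], [3]])


class TestRanksum:
    def test_separated_triplets_exact_p(self):
        assert bh.ranksum_probe([1, 2, 3], [4, 5, 6]).raw_p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert bh.ranksum_probe([2, 2, 2], [2, 2, 2]).raw_p == 1.0

    def test_exact_matches_brute_force_enumeration(self, rng):
        """Exact mode equals enumeration over all label assignments for every
        split with combined n <= 10, including ties."""
        for n1, n2 in [(3, 3), (3, 4), (4, 4), (5, 5), (3, 7)]:
            pooled = rng.integers(-3, 4, size=n1 + n2).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            mine = bh.ranksum_probe(x, y).raw_p
            # oracle: recompute the rank-sum deviation for every assignment
            ranks = stats.rankdata(pooled)
            mu = n1 * (n1 + n2 + 1) / 2
            obs = abs(stats.rankdata(pooled)[:n1].sum() - mu)
            count = total = 0
            for idx in combinations(range(n1 + n2), n1):
                total += 1
                if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-12:
                    count += 1
            if np.ptp(pooled) == 0:
                assert mine == 1.0
            else:
                assert mine == pytest.approx(count / total, abs=1e-12)

    def test_large_sample_uses_tie_corrected_normal(self, rng):
        x = rng.integers(0, 5, size=12).astype(float)
        y = rng.integers(1, 6, size=13).astype(float)
        mine = bh.ranksum_probe(x, y).raw_p
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert mine == pytest.approx(ref.pvalue, rel=1e-12)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError, match="at least 3"):
            bh.ranksum_probe([1, 2], [3, 4, 5])


class TestAnova:
    def test_identical_samples_f_zero_p_one(self):
        res = bh.compare_slopes([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.raw_p == pytest.approx(1.0)

    def test_matches_sums_of_squares_oracle(self, rng):
        """F equals the textbook between/within mean-square ratio."""
        for _ in range(25):
            a = rng.normal(0, 1, size=rng.integers(4, 12))
            b = rng.normal(0.5, 1.2, size=rng.integers(4, 12))
            res = bh.compare_slopes(a, b)
            grand = np.concatenate([a, b]).mean()
            ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
            ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            f_oracle = (ss_between / 1) / (ss_within / (a.size + b.size - 2))
            assert res.statistic == pytest.approx(f_oracle, rel=1e-10)

    def test_cohen_d_sign_follows_direction(self, rng):
        hi = rng.normal(1, 1, 20)
        lo = rng.normal(-1, 1, 20)
        assert bh.compare_slopes(hi, lo).effect_size > 0
        assert bh.compare_slopes(lo, hi).effect_size < 0


class TestAncova:
    def test_zero_covariate_truth_matches_t_test_large_n(self, rng):
        n = 2000
        g = np.repeat([1.0, 0.0], n)
        y = 0.3 * g + rng.normal(size=2 * n)
        covs = rng.normal(size=(2 * n, 2))
        mine = bh.ancova_difference_scores(y, g, covs)
        t_ref, p_ref = stats.ttest_ind(y[g == 1], y[g == 0])
        assert mine.raw_p == pytest.approx(p_ref, abs=1e-3)
        assert mine.statistic == pytest.approx(t_ref, abs=0.01)

    def test_type_i_calibration(self, rng):
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            g = np.repeat([1.0, 0.0], 15)
            y = rng.normal(size=30)
            covs = rng.normal(size=(30, 2))
            rejections += bh.ancova_difference_scores(y, g, covs).raw_p < 0.05
        rate = rejections / n_sim
        assert rate == pytest.approx(0.05, abs=2.2 * np.sqrt(0.05 * 0.95 / n_sim) + 0.01)

    def test_constant_diffs_give_null_effect(self):
        g = np.repeat([1.0, 0.0], 5)
        covs = np.arange(10, dtype=float).reshape(-1, 1)
        res = bh.ancova_difference_scores(np.full(10, 3.0), g, covs)
        assert res.raw_p == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)

    def test_singular_matrix_raises(self):
        g = np.repeat([1.0, 0.0], 5)
        with pytest.raises(ValueError, match="collinear|singular"):
            bh.ancova_difference_scores(np.arange(10.0), g, np.column_stack([g, g]))

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        n = 40
        g = (rng.random(n) < 0.5).astype(float)
        covs = rng.normal(size=(n, 2))
        y = 0.4 * g + covs @ [0.2, -0.1] + rng.normal(size=n)
        mine = bh.ancova_difference_scores(y, g, covs)
        X = sm.add_constant(np.column_stack([g, (covs - covs.mean(0)) / covs.std(0)]))
        fit = sm.OLS(y, X).fit()
        assert mine.statistic == pytest.approx(fit.tvalues[1], rel=1e-9)
        assert mine.raw_p == pytest.approx(fit.pvalues[1], rel=1e-9)


class TestOneSampleT:
    def test_symmetric_sample(self):
        res = bh.one_sample_t([-1.0, 0.0, 1.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.raw_p == pytest.approx(1.0)

    def test_closed_form_example(self):
        res = bh.one_sample_t([1, 2, 3, 4, 5])
        assert res.statistic == pytest.approx(4.2426, abs=1e-3)
        assert res.df == 4
        assert res.raw_p == pytest.approx(0.0132, abs=2e-4)

    def test_translation_invariance(self, rng):
        v = rng.normal(3, 2, size=12)
        a = bh.one_sample_t(v, mu0=1.0)
        b = bh.one_sample_t(v + 10.0, mu0=11.0)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            bh.one_sample_t([2.0, 2.0, 2.0])


class TestSlopePipeline:
    def test_noiseless_linear_residuals_recover_slope(self):
        days = [0.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        resid = pd.DataFrame({
            "subject_id": np.repeat(["a", "b"], 6),
            "group": np.repeat(["experimental", "control"], 6),
            "timepoint": np.tile(np.arange(6), 2),
            "residual": np.concatenate([0.2 * np.asarray(days), np.full(6, 1.3)]),
        })
        slopes = bh.fit_subject_slopes(resid, days)
        assert slopes[0].slope == pytest.approx(0.2, abs=1e-12)
        assert slopes[1].slope == pytest.approx(0.0, abs=1e-12)

    def test_post_equals_pre_gives_near_zero_residuals(self):
        cfg = CohortConfig(seed=4)
        cohort = simulate_cohort(cfg)
        for t in range(6):
            cohort[f"sms_mind_post_{t}"] = cohort[f"sms_mind_pre_{t}"]
        resid = bh.residualize_sms(cohort, "mind")
        assert np.abs(resid["residual"]).max() < 1e-8

    def test_covariate_recovery(self, rng):
        """Pooled residualization recovers the generative covariate effects."""
        cfg = CohortConfig(n_per_group=400, sms_noise_sd=0.15, seed=6)
        cohort = simulate_cohort(cfg)
        post = cohort[[f"sms_mind_post_{t}" for t in range(6)]].to_numpy().ravel()
        pre = cohort[[f"sms_mind_pre_{t}" for t in range(6)]].to_numpy().ravel()
        X = np.column_stack([np.ones_like(pre), pre])
        b = np.linalg.lstsq(X, post, rcond=None)[0]
        # attenuated by pre-score noise; direction and rough size must match
        assert 0.2 < b[1] < 0.7

    def test_slope_difference_recovery(self):
        """Generator slopes +-0.05 at n = 19/19 give a mean estimated group
        slope difference of ~0.10 across replicate cohorts."""
        diffs = []
        for seed in range(300):
            cohort = simulate_cohort(CohortConfig(seed=seed))
            resid = bh.residualize_sms(cohort, "mind")
            slopes = bh.fit_subject_slopes(resid, (0, 3, 4, 5, 6, 7))
            e = np.mean([s.slope for s in slopes if s.group == "experimental"])
            c = np.mean([s.slope for s in slopes if s.group == "control"])
            diffs.append(e - c)
        assert np.mean(diffs) == pytest.approx(0.10, abs=0.01)

    def test_too_few_timepoints_excluded(self):
        resid = pd.DataFrame({
            "subject_id": ["a"] * 6 + ["b"] * 6,
            "group": ["experimental"] * 12,
            "timepoint": list(range(6)) * 2,
            "residual": [0.1] * 6 + [np.nan] * 4 + [0.2, 0.3],
        })
        slopes = bh.fit_subject_slopes(resid, (0, 3, 4, 5, 6, 7))
        assert [s.subject_id for s in slopes] == ["a"]


class TestBlindingChecks:
    def test_matched_ratings_and_uncorrelated_sham_pass(self, rng):
        ratings_e = {"correspondence": rng.integers(2, 6, 19),
                     "utility": rng.integers(2, 6, 19)}
        ratings_c = {k: rng.integers(2, 6, 19) for k in ratings_e}
        displayed = rng.normal(size=18)
        actual = rng.normal(size=18)
        table = bh.blinding_checks(ratings_e, ratings_c, displayed, actual)
        assert len(table) == 3
        assert set(table["check"]) == {"ratings_correspondence", "ratings_utility",
                                       "sham_vs_actual_correlation"}
        assert table["raw_p"].between(0, 1).all()

    def test_detects_rating_imbalance(self):
        ratings_e = {"utility": np.full(10, 5.0)}
        ratings_c = {"utility": np.full(10, 1.0)}
        table = bh.blinding_checks(ratings_e, ratings_c)
        assert table["raw_p"].iloc[0] < 0.01


class TestEndpointTable:
    def test_structure_contract(self):
        table = bh.run_endpoints(simulate_cohort(CohortConfig(seed=17)))
        assert len(table) == 5
        assert list(table["endpoint"]) == list(bh.ENDPOINT_NAMES)
        assert (table["bh_adjusted_p"] >= table["raw_p"] - 1e-12).all()
        order = table["raw_p"].argsort()
        assert (np.diff(table["bh_adjusted_p"].to_numpy()[order]) >= -1e-12).all()

    def test_sms_body_null_rarely_significant(self):
        """The generator's null SMS-Body effect stays non-significant in the
        vast majority of replicate cohorts."""
        sig = 0
        n_rep = 200
        for seed in range(n_rep):
            table = bh.run_endpoints(simulate_cohort(CohortConfig(seed=seed)))
            row = table[table.endpoint == "sms_body_slope"].iloc[0]
            sig += row["bh_adjusted_p"] < 0.05
        assert sig <= 0.1 * n_rep

    def test_dass_direction_at_large_n(self):
        """With the printed group means/SDs the DASS group effect is negative
        (experimental more reduced) in every large-n replicate."""
        for seed in range(5):
            cohort = simulate_cohort(CohortConfig(n_per_group=2000, seed=seed))
            table = bh.run_endpoints(cohort)
            assert table[table.endpoint == "dass_change"]["statistic"].iloc[0] < 0

    def test_small_cohort_refused(self):
        cohort = simulate_cohort(CohortConfig(seed=1)).iloc[:5]
        with pytest.raises(ValueError, match=">= 3"):
            bh.run_endpoints(cohort)
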