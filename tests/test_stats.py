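import itertools
import math

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hst

from vascuquant.records import cohort_to_frame
from vascuquant.stats import (correlation_table, group_summary,
                              partial_spearman, spearman, wilcoxon_rank_sum)
from vascuquant.synth import CohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_ranksum_p(x, y):
    """Exact two-sided rank-sum p by explicit enumeration of assignments."""
    pooled = np.concatenate([x, y])
    ranks = st.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [sum(ranks[list(idx)])
            for idx in itertools.combinations(range(len(pooled)), n1)]
    total = len(sums)
    p_le = sum(s <= w_obs + 1e-12 for s in sums) / total
    p_ge = sum(s >= w_obs - 1e-12 for s in sums) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def brute_force_spearman_p(x, y):
    """Exact two-sided permutation p of the rank correlation (full n!)."""
    xr = st.rankdata(x)
    yr = st.rankdata(y)
    r_obs = np.corrcoef(xr, yr)[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(yr):
        r = np.corrcoef(xr, perm)[0, 1]
        count += abs(r) >= abs(r_obs) - 1e-12
        total += 1
    return count / total


# ---------------------------------------------------------------------------

class TestGroupSummary:
    def test_basic_summary(self):
        out = group_summary([1, 2, 3], ["a", "a", "a"])["a"]
        assert out == {"n": 3, "mean": 2.0, "sd": 1.0, "median": 2.0,
                       "min": 1.0, "max": 3.0}

    def test_single_value_sd_flagged(self):
        out = group_summary([5.0], ["a"])["a"]
        assert out["mean"] == 5.0 and math.isnan(out["sd"])

    def test_pooled_mean_identity(self):
        # group means 27.92 (n=13) and 35 (n=3) pool to 29.25 at 2 dp
        values = [27.92] * 13 + [35.0] * 3
        labels = ["benign"] * 13 + ["malignant"] * 3
        summ = group_summary(values, labels)
        pooled = (summ["benign"]["n"] * summ["benign"]["mean"]
                  + summ["malignant"]["n"] * summ["malignant"]["mean"]) / 16
        assert round(pooled, 2) == 29.25

    def test_missing_values_dropped(self):
        out = group_summary([1.0, float("nan"), 3.0], ["a", "a", "a"])["a"]
        assert out["n"] == 2 and out["mean"] == 2.0


class TestWilcoxonRankSum:
    def test_extreme_small_sample(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "wilcoxon_exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_fully_tied_samples(self):
        res = wilcoxon_rank_sum([7, 7, 7], [7, 7, 7])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 11 - n1))
        # occasional ties via rounding
        x = np.round(rng.normal(0, 1, n1), 1)
        y = np.round(rng.normal(0.3, 1, n2), 1)
        res = wilcoxon_rank_sum(x, y, mode="exact")
        assert res.p_value == pytest.approx(brute_force_ranksum_p(x, y),
                                            abs=1e-12)

    def test_exact_matches_enumeration_n8_n8(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        res = wilcoxon_rank_sum(x, y, mode="exact")
        assert res.p_value == pytest.approx(brute_force_ranksum_p(x, y),
                                            abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 10)
        y = rng.normal(1.0, 1, 10)
        p_exact = wilcoxon_rank_sum(x, y, mode="exact").p_value
        p_norm = wilcoxon_rank_sum(x, y, mode="normal").p_value
        assert p_norm == pytest.approx(p_exact, abs=0.02)

    @given(hst.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_p_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.5, 1, 4)
        p0 = wilcoxon_rank_sum(x, y).p_value
        p1 = wilcoxon_rank_sum(np.exp(x), np.exp(y)).p_value
        assert p0 == pytest.approx(p1, abs=1e-12)

    def test_permutation_distribution_sums_to_one(self):
        # tail probabilities of the enumerated distribution are coherent
        x, y = [1.0, 2.0, 5.0], [3.0, 4.0]
        ranks = st.rankdata(np.concatenate([x, y]))
        sums = [sum(ranks[list(idx)])
                for idx in itertools.combinations(range(5), 3)]
        probs = {s: sums.count(s) / len(sums) for s in set(sums)}
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == 1.0
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).statistic == -1.0

    def test_small_example_against_oracle(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        res = spearman(x, y, mode="exact")
        assert res.statistic == pytest.approx(0.6)
        assert res.p_value == pytest.approx(brute_force_spearman_p(x, y),
                                            abs=1e-12)

    @pytest.mark.parametrize("seed,n", [(0, 5), (1, 6), (2, 7), (3, 7)])
    def test_exact_p_matches_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(0, 1, n), 1)  # rounding produces ties
        y = np.round(0.5 * x + rng.normal(0, 1, n), 1)
        res = spearman(x, y, mode="exact")
        assert res.p_value == pytest.approx(brute_force_spearman_p(x, y),
                                            abs=1e-12)

    def test_r_matches_scipy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 16)
        y = 0.5 * x + rng.normal(0, 1, 16)
        res = spearman(x, y)
        assert res.method == "spearman_mc"
        assert res.statistic == pytest.approx(st.spearmanr(x, y).statistic)

    def test_t_approximation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 30)
        y = 0.6 * x + rng.normal(0, 1, 30)
        res = spearman(x, y, mode="t_approx")
        ref = st.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0]
        res = spearman(x, y)
        assert res.n_used == 3 and res.missing_excluded == 2
        assert res.statistic == 1.0

    def test_zero_rank_variance_flagged(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.method == "undefined" and math.isnan(res.statistic)

    @given(hst.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 7)
        y = rng.normal(0, 1, 7)
        r0 = spearman(x, y, mode="exact")
        r1 = spearman(np.exp(x), y ** 3, mode="exact")
        assert r0.statistic == pytest.approx(r1.statistic, abs=1e-12)
        assert -1.0 <= r0.statistic <= 1.0


class TestPartialSpearman:
    def test_perfect_association_survives_partialling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 20)
        cov = rng.normal(0, 1, 20)
        res = partial_spearman(x, x.copy(), cov)
        assert res.statistic == pytest.approx(1.0)

    def test_covariate_identical_to_y_flagged(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 1, 15)
        res = partial_spearman(x, y, y.copy())
        assert res.method == "undefined"

    def test_independent_covariate_leaves_marginal_r(self):
        rng = np.random.default_rng(3)
        n = 1000
        x = rng.normal(0, 1, n)
        y = 0.6 * x + rng.normal(0, 1, n)
        cov = rng.normal(0, 1, n)
        partial = partial_spearman(x, y, cov).statistic
        marginal = spearman(x, y, mode="t_approx").statistic
        assert abs(partial - marginal) < 0.05

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(4)
        n = 40
        df = pd.DataFrame({"x": rng.normal(0, 1, n)})
        df["z"] = 0.4 * df["x"] + rng.normal(0, 1, n)
        df["y"] = 0.5 * df["x"] + 0.3 * df["z"] + rng.normal(0, 1, n)
        res = partial_spearman(df["x"], df["y"], df["z"])
        ref = pg.partial_corr(df, x="x", y="y", covar="z",
                              method="spearman")
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]),
                                              abs=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]),
                                            abs=1e-6)

    def test_controls_for_confounder(self):
        # x and y associate only through the covariate
        rng = np.random.default_rng(5)
        n = 500
        cov = rng.normal(0, 1, n)
        x = cov + rng.normal(0, 0.5, n)
        y = cov + rng.normal(0, 0.5, n)
        marginal = spearman(x, y, mode="t_approx").statistic
        partial = partial_spearman(x, y, cov).statistic
        assert marginal > 0.5
        assert abs(partial) < 0.15


class TestCorrelationTable:
    def test_comonotone_cohort_has_unit_cells(self):
        df = cohort_to_frame(generate_cohort(CohortSpec(
            n_benign=10, n_malignant=0, latent_spearman_rho=1.0, seed=6)))
        table = correlation_table(df, ["quotient"], ["cd34_fraction"])
        assert table[("quotient", "cd34_fraction")].statistic == 1.0

    def test_tiny_cohort_flagged(self):
        df = cohort_to_frame(generate_cohort(CohortSpec(
            n_benign=2, n_malignant=0, seed=1)))
        table = correlation_table(df, ["quotient"], ["cd34_fraction"])
        assert table[("quotient", "cd34_fraction")].method == "undefined"

    def test_latent_rho_recovered(self):
        df = cohort_to_frame(generate_cohort(CohortSpec(
            n_benign=406, n_malignant=94, latent_spearman_rho=0.55, seed=1)))
        res = correlation_table(df, ["quotient"], ["cd34_fraction"],
                                mode="t_approx")[("quotient", "cd34_fraction")]
        assert res.statistic == pytest.approx(0.55, abs=0.10)

    def test_raw_p_values_only(self):
        # no multiple-testing adjustment: each cell equals its standalone test
        df = cohort_to_frame(generate_cohort(CohortSpec(seed=9)))
        table = correlation_table(df, ["quotient"], ["cd34_fraction"])
        solo = spearman(df["quotient"], df["cd34_fraction"])
        cell = table[("quotient", "cd34_fraction")]
        assert cell.p_value == solo.p_value


class TestNullCalibration:
    def test_exact_test_type_i_error_at_study_size(self):
        # 400 null cohorts of 13 + 3: rejection rate of the exact test at
        # alpha = 0.05 stays near (conservatively below) the nominal level
        rejections = 0
        n_sims = 400
        for seed in range(1, n_sims + 1):
            spec = CohortSpec(n_benign=13, n_malignant=3,
                              latent_spearman_rho=0.0,
                              malignant_quotient_mean=0.88,
                              malignant_quotient_sd=0.89,
                              malignant_cd34_mean=0.05,
                              malignant_cd34_sd=0.05, seed=seed)
            df = cohort_to_frame(generate_cohort(spec))
            x = df.loc[df.label == "benign", "quotient"]
            y = df.loc[df.label == "malignant", "quotient"]
            if wilcoxon_rank_sum(x, y).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.08
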