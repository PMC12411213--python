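"""Statistics oracles: logistic IRLS, splits, AUROC, DeLong, Fisher, Wilcoxon.

Independent cross-checks: brute-force enumeration oracles written inline,
plus scipy / scikit-learn / statsmodels where they implement the same
quantity.  The frozen DeLong reference values were computed with R's pROC
(roc.test, method="delong", paired) on the identical dataset.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nwuct.errors import (
    CollinearityError,
    DegenerateLabelError,
    DegenerateOutcomeError,
    PairingError,
    ParameterError,
)
from nwuct.outcome_stats import (
    ModelComparison,
    auroc,
    compare_models,
    delong_test,
    delong_variance,
    describe_cohort,
    fisher_exact_2x2,
    fit_logistic,
    format_percent,
    median_iqr,
    stratified_split,
    wilcoxon_rank_sum,
)
from nwuct.phantom import CohortModel, generate_cohort


def pair_counting_auroc(scores, labels):
    """Brute force over all positive-negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert auroc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_eight_subject_hand_example(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.2, 0.7, 0.4]
        labels = [0, 0, 1, 1, 0, 0, 1, 1]
        assert auroc(scores, labels) == pytest.approx(
            pair_counting_auroc(scores, labels), abs=1e-12)

    def test_matches_pair_counting_on_many_small_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(3, 13)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, rng.integers(1, n), replace=False)] = 1
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            assert auroc(scores, labels) == pytest.approx(
                pair_counting_auroc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        scores = rng.normal(size=300)
        labels = (rng.random(300) < 0.4).astype(int)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelError):
            auroc([1, 2, 3], [1, 1, 1])


class TestDelong:
    def test_identical_models_give_z_zero_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=50)
        y = (rng.random(50) < 0.5).astype(int)
        r = delong_test(s, s.copy(), y)
        assert r.z == 0.0 and r.p_two_sided == 1.0

    def test_matches_frozen_proc_reference(self):
        """z and p agree with R pROC roc.test(method='delong') to 1e-9."""
        rng = np.random.default_rng(42)
        n = 40
        labels = np.array([1] * 18 + [0] * 22)
        sa = labels * 1.0 + rng.normal(0, 1.2, n)
        sb = labels * 0.8 + 0.5 * sa + rng.normal(0, 1.0, n)
        assert auroc(sa, labels) == pytest.approx(0.717171717172, abs=1e-9)
        assert auroc(sb, labels) == pytest.approx(0.888888888889, abs=1e-9)
        r = delong_test(sa, sb, labels)
        assert r.z == pytest.approx(-2.064169119104, abs=1e-9)
        assert r.p_two_sided == pytest.approx(0.039001684347, abs=1e-9)

    def test_variance_matches_stratified_bootstrap(self):
        """DeLong variance of one AUROC vs 20,000-rep bootstrap at n=30."""
        rng = np.random.default_rng(7)
        m, n = 14, 16
        pos = rng.normal(1.0, 1.0, m)
        neg = rng.normal(0.0, 1.0, n)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * m + [0] * n)
        v_delong = delong_variance(scores, labels)
        reps = 20000
        bi = rng.integers(0, m, (reps, m))
        bj = rng.integers(0, n, (reps, n))
        aucs = np.empty(reps)
        for r in range(reps):
            p = pos[bi[r]]
            q = neg[bj[r]]
            cmp = (p[:, None] > q[None, :]) + 0.5 * (p[:, None] == q[None, :])
            aucs[r] = cmp.mean()
        v_boot = aucs.var(ddof=1)
        assert v_delong == pytest.approx(v_boot, rel=0.15)

    def test_type_one_error_calibration(self):
        """Null rejection rate at alpha=0.05 over 2,000 simulated datasets."""
        rng = np.random.default_rng(2024)
        rejections = 0
        sims = 2000
        for _ in range(sims):
            y = np.array([1] * 50 + [0] * 50)
            sa = rng.normal(size=100)
            sb = rng.normal(size=100)
            r = delong_test(sa, sb, y)
            rejections += r.p_two_sided < 0.05
        assert 0.035 <= rejections / sims <= 0.065

    def test_unequal_lengths_rejected(self):
        with pytest.raises(PairingError):
            delong_test([1, 2, 3], [1, 2], [1, 0, 1])

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelError):
            delong_test([1, 2], [2, 1], [1, 1])


class TestFisher:
    def test_homogeneous_table(self):
        oratio, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert oratio == 1.0 and p == 1.0

    def test_enumeration_example_matches_scipy(self):
        table = [[1, 9], [11, 3]]
        oratio, p = fisher_exact_2x2(table)
        res = sps.fisher_exact(table)
        assert p == pytest.approx(res.pvalue, abs=1e-12)
        assert oratio == pytest.approx((1 * 3) / (9 * 11))

    def test_many_random_tables_match_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            t = rng.integers(0, 12, (2, 2))
            if t.sum() == 0:
                continue
            _, p = fisher_exact_2x2(t)
            assert p == pytest.approx(sps.fisher_exact(t).pvalue, abs=1e-10)

    def test_simultaneous_row_column_swap_invariance(self):
        t = np.array([[2, 7], [8, 1]])
        _, p1 = fisher_exact_2x2(t)
        _, p2 = fisher_exact_2x2(t[::-1, ::-1])
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_zero_cell_uses_haldane_odds_ratio(self):
        oratio, _ = fisher_exact_2x2([[0, 10], [5, 5]])
        assert oratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestWilcoxon:
    def test_identical_samples_with_ties(self):
        x = [1, 2, 2, 3, 5]
        _, p = wilcoxon_rank_sum(x, list(x))
        assert p >= 0.99

    def test_exact_enumeration_four_vs_four(self):
        x = [1.2, 3.4, 5.1, 9.0]
        y = [0.5, 2.2, 4.4, 6.6]
        u, p = wilcoxon_rank_sum(x, y)
        # oracle: all C(8,4)=70 assignments of ranks
        ranks = sps.rankdata(np.concatenate([x, y]))
        mu = 8.0
        obs_dev = abs((sum(ranks[:4]) - 10) - mu)
        count = 0
        for comb in itertools.combinations(range(8), 4):
            u_perm = sum(ranks[list(comb)]) - 10
            count += abs(u_perm - mu) >= obs_dev - 1e-12
        assert p == pytest.approx(count / 70.0, abs=1e-12)
        res = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        assert u == res.statistic
        assert p == pytest.approx(res.pvalue, abs=1e-12)

    def test_role_inversion_preserves_p(self):
        x = [3.0, 5.5, 1.1, 9.9, 2.0]
        y = [4.0, 4.4, 8.8]
        ux, px = wilcoxon_rank_sum(x, y)
        uy, py = wilcoxon_rank_sum(y, x)
        assert px == pytest.approx(py, abs=1e-12)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_large_sample_approximation_tracks_scipy(self):
        rng = np.random.default_rng(9)
        x = np.round(rng.normal(0.0, 1.0, 40), 1)
        y = np.round(rng.normal(0.6, 1.0, 35), 1)
        _, p = wilcoxon_rank_sum(x, y)
        res = sps.mannwhitneyu(x, y, method="asymptotic",
                               alternative="two-sided")
        assert p == pytest.approx(res.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            wilcoxon_rank_sum([], [1.0])


class TestLogistic:
    def test_null_predictor_coefficient_near_zero(self):
        rng = np.random.default_rng(21)
        n = 4000
        t = pd.DataFrame({"x": rng.normal(size=n),
                          "outcome": rng.binomial(1, 0.5, n)})
        fit = fit_logistic(t, "outcome", ["x"])
        assert abs(fit.coefficients["x"]) < 0.1

    def test_beats_grid_search_oracle_on_six_rows(self):
        """ML fit log-likelihood >= every point of a dense coefficient grid."""
        t = pd.DataFrame({"x": [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0, -1.5, 0.1,
                                0.9, 1.7],
                          "outcome": [0, 0, 1, 0, 1, 1, 0, 0, 1, 1]})
        fit = fit_logistic(t, "outcome", ["x"])
        b0 = np.arange(-5, 5.0001, 0.01)
        b1 = np.arange(-5, 5.0001, 0.01)
        B0, B1 = np.meshgrid(b0, b1, indexing="ij")
        x = t.x.to_numpy()[None, None, :]
        y = t.outcome.to_numpy()[None, None, :]
        eta = B0[..., None] + B1[..., None] * x
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=-1)
        assert fit.log_likelihood >= ll.max() - 1e-9

    def test_matches_statsmodels_on_cohort(self):
        import statsmodels.api as sm

        t = generate_cohort(800, seed=6)
        cols = ["age", "nihss", "tpa", "evt", "avg_nwu"]
        fit = fit_logistic(t, "outcome", cols)
        X = sm.add_constant(t[cols].to_numpy(float))
        ref = sm.Logit(t.outcome.to_numpy(float), X).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients.to_numpy(), ref.params,
                                   atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors.to_numpy(), ref.bse,
                                   rtol=1e-4)

    def test_deviance_never_increases(self):
        t = generate_cohort(400, seed=8)
        fit = fit_logistic(t, "outcome", ["age", "nihss", "avg_nwu"])
        path = np.asarray(fit.deviance_path)
        assert np.all(np.diff(path) <= 1e-9)

    def test_ci_contains_odds_ratio_and_matches_wald_formula(self):
        t = generate_cohort(600, seed=10)
        fit = fit_logistic(t, "outcome", ["avg_nwu"])
        orr = fit.odds_ratios["avg_nwu"]
        lo, hi = fit.ci95.loc["avg_nwu"]
        assert lo < orr < hi
        se = fit.standard_errors["avg_nwu"]
        assert lo == pytest.approx(orr * np.exp(-1.96 * se))

    def test_constant_outcome_rejected(self):
        t = pd.DataFrame({"x": np.arange(20.0), "outcome": [1] * 20})
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(t, "outcome", ["x"])

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        t = pd.DataFrame({"a": x, "b": 2 * x,
                          "outcome": (x > 0).astype(int)})
        with pytest.raises(CollinearityError):
            fit_logistic(t, "outcome", ["a", "b"])

    def test_separation_flagged_not_raised(self):
        t = pd.DataFrame({"x": np.r_[np.arange(10.0), np.arange(10.0) + 20],
                          "outcome": [0] * 10 + [1] * 10})
        fit = fit_logistic(t, "outcome", ["x"])
        assert not fit.converged

    def test_missing_rows_dropped(self):
        t = generate_cohort(100, seed=12).copy()
        t.loc[t.index[:7], "avg_nwu"] = np.nan
        fit = fit_logistic(t, "outcome", ["avg_nwu", "age"])
        assert fit.n_used == 93


class TestStratifiedSplit:
    def test_eighty_twenty_counts_from_the_stated_rule(self):
        t = pd.DataFrame({"outcome": [1] * 40 + [0] * 60,
                          "x": np.arange(100.0)})
        train, test = stratified_split(t, seed=0)
        assert (test.outcome == 1).sum() == 8
        assert (test.outcome == 0).sum() == 12
        assert len(train) == 80

    def test_same_seed_same_partition(self):
        t = generate_cohort(150, seed=1)
        tr1, te1 = stratified_split(t, seed=5)
        tr2, te2 = stratified_split(t, seed=5)
        assert te1.index.equals(te2.index)
        tr3, te3 = stratified_split(t, seed=6)
        assert not te1.index.equals(te3.index)

    def test_partition_is_disjoint_and_exhaustive(self):
        t = generate_cohort(123, seed=2)
        train, test = stratified_split(t, seed=1)
        assert len(train) + len(test) == len(t)
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(t.index)

    def test_exact_half_ties_break_toward_larger_class(self):
        t = pd.DataFrame({"outcome": [1] * 10 + [0] * 6})
        _, test = stratified_split(t, test_fraction=0.25, seed=0)
        # 10*0.25 = 2.5 -> 3 (larger class up); 6*0.25 = 1.5 -> 1 (down)
        assert (test.outcome == 1).sum() == 3
        assert (test.outcome == 0).sum() == 1


class TestCompareModels:
    def test_identical_predictor_sets(self):
        t = generate_cohort(400, seed=3)
        comp = compare_models(t, ["age", "avg_nwu"], ["age", "avg_nwu"],
                              seed=1)
        assert isinstance(comp, ModelComparison)
        assert comp.auroc_a == comp.auroc_b
        assert comp.delong_p == 1.0

    def test_signal_beats_noise_in_most_replicates(self):
        """Biomarker with true effect vs pure noise: one-sided power check."""
        wins = 0
        rejections = 0
        reps = 60
        rng = np.random.default_rng(99)
        for i in range(reps):
            t = generate_cohort(3000, CohortModel(beta_nwu=0.2), seed=1000 + i)
            t = t.assign(noise_marker=rng.normal(size=len(t)))
            comp = compare_models(t, ["avg_nwu"], ["noise_marker"],
                                  seed=1000 + i)
            wins += comp.auroc_a > comp.auroc_b
            rejections += comp.delong_p < 0.05
        assert wins / reps >= 0.95
        assert rejections / reps >= 0.90

    def test_equal_signal_biomarkers_reject_at_alpha(self):
        """Two equally informative noisy copies of one latent marker."""
        rejections = 0
        reps = 100
        rng = np.random.default_rng(7)
        for i in range(reps):
            t = generate_cohort(1500, CohortModel(beta_nwu=0.15), seed=2000 + i)
            latent = t.avg_nwu.to_numpy()
            t = t.assign(marker_a=latent + rng.normal(0, 2.0, len(t)),
                         marker_b=latent + rng.normal(0, 2.0, len(t)))
            comp = compare_models(t, ["marker_a"], ["marker_b"], seed=2000 + i)
            rejections += comp.delong_p < 0.05
        assert rejections / reps <= 0.12


class TestDescribeCohort:
    def test_percentage_formatting_to_one_decimal(self):
        assert format_percent(139, 157) == "139 (88.5%)"
        assert format_percent(198, 402) == "198 (49.3%)"

    def test_median_iqr_of_one_to_five(self):
        med, q1, q3 = median_iqr([1, 2, 3, 4, 5])
        assert (med, q1, q3) == (3.0, 2.0, 4.0)

    def test_summary_table_shape_and_tests(self):
        t = generate_cohort(300, seed=4)
        summary = describe_cohort(t, "outcome",
                                  value_cols=["age", "nihss", "tpa", "evt"])
        assert list(summary.index) == ["age", "nihss", "tpa", "evt"]
        assert summary.p_value.between(0, 1).all()
        assert "(" in summary.loc["tpa", "overall"]
        assert "[" in summary.loc["age", "overall"]

    def test_empty_group_is_an_error(self):
        t = generate_cohort(50, seed=5).copy()
        t["grp"] = 0
        with pytest.raises(ParameterError):
            describe_cohort(t, "grp")


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.integers(0, 30), min_size=2, max_size=12),
       st.data())
def test_auroc_pair_counting_equivalence_property(scores, data):
    labels = data.draw(st.lists(st.integers(0, 1), min_size=len(scores),
                                max_size=len(scores)))
    if 0 < sum(labels) < len(labels):
        assert auroc(scores, labels) == pytest.approx(
            pair_counting_auroc(scores, labels), abs=1e-12)
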