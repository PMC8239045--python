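import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.base import clone

from regulonet import (GuanRankRidge, Parameters, SurvivalTable,
                       compare_feature_spaces, cox_univariate, evaluate_risk,
                       fit_risk_model, guanrank, high_risk_labels,
                       univariate_screen)


def _survival(durations, events, ids=None):
    ids = ids or [f"p{i}" for i in range(len(durations))]
    return SurvivalTable(pd.DataFrame({
        "sample_id": ids, "duration": durations, "event": events}))


class TestGuanRank:
    def test_uncensored_events_rank_by_time(self):
        s = guanrank(_survival([10, 20, 30], [True, True, True]))
        assert s.tolist() == [1.0, 0.5, 0.0]

    def test_event_before_censoring_is_certainly_higher_risk(self):
        s = guanrank(_survival([10, 15], [True, False]))
        assert s.tolist() == [1.0, 0.0]

    def test_tied_event_times_score_equally(self):
        s = guanrank(_survival([10, 10, 50], [True, True, True]))
        assert s["p0"] == s["p1"] == 1.0

    def test_reduces_to_reversed_rank_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(100, size=40)
        s = guanrank(_survival(t, [True] * 40))
        expected = rankdata(-t)
        expected = (expected - expected.min()) / np.ptp(expected)
        assert np.allclose(s.to_numpy(), expected)

    def test_monotone_decreasing_in_event_time(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.exponential(100, size=30))
        e = rng.random(30) < 0.6
        s = guanrank(_survival(t, e)).to_numpy()
        uncensored = np.flatnonzero(e)
        assert np.all(np.diff(s[uncensored]) <= 1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            guanrank(_survival([5.0], [True]))


class TestEvaluateRisk:
    def _scores(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.random(n), index=[f"p{i}" for i in range(n)])

    def test_perfect_predictor_scores_one(self):
        g = self._scores()
        assert evaluate_risk(g, g) == 1.0

    def test_constant_predictor_scores_half(self):
        g = self._scores()
        const = pd.Series(0.5, index=g.index)
        assert evaluate_risk(const, g) == 0.5

    def test_reversed_predictor_scores_zero(self):
        g = self._scores()
        assert evaluate_risk(-g, g) == 0.0

    def test_degenerate_labels_rejected(self):
        g = self._scores(n=3)
        with pytest.raises(ValueError, match="class"):
            evaluate_risk(g, g, label_frac=0.99)


def _risk_cohort(hazard_beta=2.0, seed=11, n=300, n_features=20):
    """Features tracking a latent program whose activity drives the hazard."""
    rng = np.random.default_rng(seed)
    activity = rng.standard_normal(n)
    X = pd.DataFrame(
        {f"f{k}": activity + rng.normal(0, 0.7, n) for k in range(5)}
        | {f"n{k}": rng.standard_normal(n) for k in range(n_features - 5)},
        index=[f"p{i}" for i in range(n)])
    rates = np.exp(hazard_beta * activity) / 365
    t = rng.exponential(1 / rates)
    c = rng.exponential(365 * 2, size=n)
    surv = _survival(np.minimum(t, c), t <= c, ids=list(X.index))
    return X, guanrank(surv)


class TestGuanRankRidge:
    def test_strong_hazard_signal_reaches_high_auc(self):
        X, scores = _risk_cohort(hazard_beta=2.0, seed=11)
        model = GuanRankRidge(n_repeats=100, random_state=0).fit(X, scores)
        assert model.cv_mean_auc_ >= 0.85

    def test_permuted_scores_give_chance_auc(self):
        X, scores = _risk_cohort(hazard_beta=2.0, seed=12)
        rng = np.random.default_rng(0)
        permuted = pd.Series(rng.permutation(scores.to_numpy()),
                             index=scores.index)
        model = GuanRankRidge(n_repeats=100, random_state=0).fit(X, permuted)
        assert 0.45 <= model.cv_mean_auc_ <= 0.55

    def test_middle_risk_samples_still_predicted(self):
        X, scores = _risk_cohort(seed=13)
        model = fit_risk_model(X, scores, Parameters(ridge_repeats=50),
                               seed=0)
        middle = scores.sort_values().index[len(scores) // 2]
        assert middle not in model.training_samples_
        preds = model.predict(X)
        assert np.isfinite(preds).all() and len(preds) == len(X)

    def test_coefficients_invariant_to_sample_order(self):
        X, scores = _risk_cohort(seed=14, n=120)
        m1 = GuanRankRidge(n_repeats=30, random_state=0).fit(X, scores)
        perm = list(np.random.default_rng(1).permutation(X.index))
        m2 = GuanRankRidge(n_repeats=30, random_state=0).fit(
            X.loc[perm], scores.loc[perm])
        assert np.allclose(m1.coef_, m2.coef_)
        assert m1.alpha_ == m2.alpha_

    def test_too_few_training_samples_rejected(self):
        X, scores = _risk_cohort(seed=15, n=300)
        model = GuanRankRidge(n_repeats=5)
        with pytest.raises(ValueError, match="10 training samples"):
            model.fit(X.iloc[:8], scores.iloc[:8])

    def test_sklearn_clone_contract(self):
        model = GuanRankRidge(n_repeats=7, random_state=3)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()

    def test_larger_alpha_grid_cannot_hurt_selection(self):
        X, scores = _risk_cohort(seed=16, n=150)
        small = GuanRankRidge(alphas=[0.1, 1.0], n_repeats=30,
                              random_state=0).fit(X, scores)
        large = GuanRankRidge(alphas=[0.1, 1.0, 10.0, 100.0], n_repeats=30,
                              random_state=0).fit(X, scores)
        assert large.cv_mean_auc_ >= small.cv_mean_auc_ - 1e-12


class TestCoxUnivariate:
    def test_two_group_rate_ratio_recovered(self):
        rng = np.random.default_rng(0)
        n = 500
        grp = rng.integers(0, 2, n).astype(float)
        rates = np.where(grp == 1, 3.0, 1.0) / 365
        surv = _survival(rng.exponential(1 / rates), [True] * n)
        res = cox_univariate(pd.Series(grp, index=surv.sample_ids), surv)
        assert 2.5 <= res.hazard_ratio <= 3.6

    def test_negated_covariate_inverts_hazard_ratio(self):
        rng = np.random.default_rng(1)
        n = 200
        x = rng.standard_normal(n)
        surv = _survival(rng.exponential(100 * np.exp(-0.5 * x)), [True] * n)
        x = pd.Series(x, index=surv.sample_ids)
        hr = cox_univariate(x, surv).hazard_ratio
        hr_neg = cox_univariate(-x, surv).hazard_ratio
        assert hr_neg == pytest.approx(1.0 / hr, rel=1e-6)

    def test_constant_covariate_rejected(self):
        surv = _survival([10, 20, 30], [True, True, True])
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(pd.Series(1.0, index=surv.sample_ids), surv)


class TestCompareFeatureSpaces:
    def test_identical_spaces_give_identical_distributions(self):
        X, scores = _risk_cohort(seed=20, n=100)
        params = Parameters(split_repeats=20)
        cmp = compare_feature_spaces(X, X, scores, list(X.index), params,
                                     seed=0)
        assert np.allclose(cmp.auc_expression, cmp.auc_network)

    def test_denoised_space_wins_paired_test(self):
        rng = np.random.default_rng(21)
        n = 200
        latent = rng.standard_normal(n)
        idx = [f"p{i}" for i in range(n)]
        noisy = pd.DataFrame(
            {"risk_gene": latent + rng.normal(0, 1.5, n)}
            | {f"n{k}": rng.standard_normal(n) for k in range(20)}, index=idx)
        denoised = noisy.copy()
        denoised["risk_gene"] = latent + rng.normal(0, 0.3, n)
        rates = np.exp(1.5 * latent) / 365
        surv = _survival(rng.exponential(1 / rates), [True] * n, ids=idx)
        scores = guanrank(surv)
        cmp = compare_feature_spaces(noisy, denoised, scores, idx,
                                     Parameters(split_repeats=100), seed=0)
        assert cmp.mean_network > cmp.mean_expression
        assert cmp.paired_p() < 0.05

    def test_subtype_too_small_rejected(self):
        X, scores = _risk_cohort(seed=22, n=100)
        with pytest.raises(ValueError, match="20 samples"):
            compare_feature_spaces(X, X, scores, list(X.index)[:10])


class TestUnivariateScreen:
    def test_identical_spaces_intersect_fully(self):
        X, scores = _risk_cohort(seed=30, n=100)
        res = univariate_screen(X, X, scores, top_n=5)
        assert set(res.intersection) == set(res.top_expression)
        assert len(res.intersection) == 5

    def test_independent_spaces_intersect_at_chance(self):
        rng = np.random.default_rng(31)
        n, g = 120, 1000
        idx = [f"p{i}" for i in range(n)]
        cols = [f"g{k}" for k in range(g)]
        a = pd.DataFrame(rng.standard_normal((n, g)), index=idx, columns=cols)
        b = pd.DataFrame(rng.standard_normal((n, g)), index=idx, columns=cols)
        scores = pd.Series(rng.random(n), index=idx)
        res = univariate_screen(a, b, scores, top_n=100)
        # hypergeometric expectation: 100*100/1000 = 10 shared genes
        assert 1 <= len(res.intersection) <= 25

    def test_permuted_reference_near_chance(self):
        X, scores = _risk_cohort(seed=32, n=150)
        res = univariate_screen(X, X, scores, top_n=5,
                                holdout=(X, scores), seed=0)
        assert res.permuted_reference_auc == pytest.approx(0.5, abs=0.1)

    def test_top_n_bounded_by_gene_count(self):
        X, scores = _risk_cohort(seed=33, n=60)
        with pytest.raises(ValueError, match="top_n"):
            univariate_screen(X, X, scores, top_n=10_000)


class TestHighRiskLabels:
    def test_top_fraction_labeled(self):
        scores = pd.Series(np.arange(10, dtype=float),
                           index=[f"p{i}" for i in range(10)])
        labels = high_risk_labels(scores, 0.2)
        assert labels.sum() == 2 and labels["p9"] and labels["p8"]
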