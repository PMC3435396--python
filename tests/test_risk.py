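"""Logistic risk models, calibration diagnostics and the risk diagram."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kbas.risk import (
    c_statistic,
    fit_logistic,
    hosmer_lemeshow,
    overall_score_model,
    pairwise_interaction_design,
    risk_bin_diagram,
    stepwise_select,
)
from kbas.scoring import SnpModel


class TestOverallScoreModel:
    def test_union_weights_one(self):
        a = SnpModel(["x", "y", "z"], [1, 1, 1])
        b = SnpModel(["p", "q", "r"], [1, 0, 1])
        m = overall_score_model([a, b])
        assert m.snp_ids == ["x", "y", "z", "p", "r"]
        assert m.weights == [1] * 5

    def test_idempotent_and_dedup(self):
        a = SnpModel(["x", "y", "z"], [1, 2, 1], bits_per_weight=2)
        assert overall_score_model([a, a]).snp_ids == ["x", "y", "z"]
        b = SnpModel(["z", "w", "v"], [1, 1, 1])
        assert overall_score_model([a, b]).snp_ids == ["x", "y", "z", "w", "v"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overall_score_model([])


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # exposed: 30 cases / 10 controls; unexposed: 10 cases / 30 controls
        x = np.array([1] * 40 + [0] * 40, float)
        y = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30, float)
        fit = fit_logistic(x[:, None], y, ["exposed"])
        log_or = math.log((30 * 30) / (10 * 10))
        assert fit.coefficients[1] == pytest.approx(log_or, abs=1e-6)
        assert fit.odds_ratios[1] == pytest.approx(9.0, abs=1e-4)
        # Woolf SE of the 2x2 log odds ratio
        se = math.sqrt(1 / 30 + 1 / 10 + 1 / 10 + 1 / 30)
        assert fit.standard_errors[1] == pytest.approx(se, rel=1e-4)

    def test_uninformative_predictors_null(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200).astype(float)
        # constant column: no information beyond the intercept, Wald p ~ 1
        fit = fit_logistic(np.ones((200, 1)), y, ["const2"])
        assert fit.p_values[1] > 0.9
        # independent noise column: estimate near zero
        x = rng.normal(size=200)
        fit = fit_logistic(x[:, None], y, ["noise"])
        assert abs(fit.coefficients[1]) < 3 * fit.standard_errors[1]

    def test_simulated_recovery_vs_independent_reference(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(42)
        n = 2000
        x = rng.normal(size=n)
        eta = -0.4 + 0.8 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(x[:, None], y, ["x"])
        # within 3 SE of the truth
        assert abs(fit.coefficients[1] - 0.8) < 3 * fit.standard_errors[1]
        assert abs(fit.coefficients[0] + 0.4) < 3 * fit.standard_errors[0]
        ref = LogisticRegression(C=1e10, tol=1e-10, max_iter=2000).fit(x[:, None], y)
        assert fit.coefficients[1] == pytest.approx(ref.coef_[0][0], abs=1e-5)
        assert fit.coefficients[0] == pytest.approx(ref.intercept_[0], abs=1e-5)

    def test_perfect_separation_flagged(self):
        x = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
        y = np.array([0, 0, 0, 1, 1, 1], float)
        fit = fit_logistic(x[:, None], y, ["x"])
        assert not fit.converged

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((3, 1)), [0, 1, 2])


class TestStepwise:
    def _design(self, rng, n, n_noise):
        cols = {"signal": rng.normal(size=n)}
        for j in range(n_noise):
            cols[f"noise{j}"] = rng.normal(size=n)
        return pd.DataFrame(cols)

    def test_strong_predictor_kept_noise_rarely(self):
        rng = np.random.default_rng(7)
        kept_signal, kept_noise, total_noise = 0, 0, 0
        reps = 40
        for _ in range(reps):
            X = self._design(rng, 400, 5)
            eta = -0.2 + 1.2 * X["signal"].to_numpy()
            y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = stepwise_select(X, y)
            kept_signal += "signal" in fit.terms
            kept_noise += sum(t.startswith("noise") for t in fit.terms)
            total_noise += 5
        assert kept_signal == reps
        # each noise term enters with probability ~ entry_p = 0.05
        rate = kept_noise / total_noise
        band = 3 * math.sqrt(0.05 * 0.95 / total_noise)
        assert rate < 0.05 + band + 0.02

    def test_all_noise_majority_intercept_only(self):
        rng = np.random.default_rng(8)
        intercept_only = 0
        for _ in range(30):
            X = self._design(rng, 300, 4)[[f"noise{j}" for j in range(4)]]
            y = (rng.random(300) < 0.4).astype(float)
            fit = stepwise_select(X, y)
            intercept_only += fit.terms == ["intercept"]
        assert intercept_only > 15

    def test_empty_design_gives_intercept_fit(self):
        y = np.array([0, 1, 0, 1, 1], float)
        fit = stepwise_select(pd.DataFrame(index=range(5)), y)
        assert fit.terms == ["intercept"]
        assert fit.coefficients[0] == pytest.approx(math.log(3 / 2), abs=1e-6)

    def test_interaction_design_columns(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0]})
        out = pairwise_interaction_design(df)
        assert list(out.columns) == ["a", "b", "c", "a*b", "a*c", "b*c"]
        assert out["a*b"].tolist() == [3.0, 8.0]


class TestHosmerLemeshow:
    def test_df_is_groups_minus_two(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 500)
        y = (rng.random(500) < p).astype(float)
        chi2, df, pval = hosmer_lemeshow(p, y, n_groups=10)
        assert df == 8
        assert pval > 0.001  # well-calibrated by construction

    def test_perfect_calibration_gives_zero(self):
        # observed equals expected exactly in each group
        p = np.repeat([0.2, 0.5, 0.8], 10)
        y = np.concatenate([[1] * 2 + [0] * 8, [1] * 5 + [0] * 5, [1] * 8 + [0] * 2])
        chi2, df, pval = hosmer_lemeshow(p, y, n_groups=3)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert pval == pytest.approx(1.0)

    def test_three_group_hand_computation(self):
        p = np.array([0.1] * 10 + [0.5] * 10 + [0.9] * 10)
        y = np.array([1] * 3 + [0] * 7 + [1] * 4 + [0] * 6 + [1] * 10)
        chi2, df, pval = hosmer_lemeshow(p, y, n_groups=3)
        expected = (
            (3 - 1.0) ** 2 / (1.0 * (1 - 0.1))
            + (4 - 5.0) ** 2 / (5.0 * (1 - 0.5))
            + (10 - 9.0) ** 2 / (9.0 * (1 - 0.9))
        )
        assert chi2 == pytest.approx(expected, rel=1e-10)
        assert df == 1
        assert pval == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-10)

    def test_min_groups(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5, 0.5], [0, 1], n_groups=2)


class TestCStatistic:
    def test_perfect_and_all_ties(self):
        assert c_statistic([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
        assert c_statistic([5.0] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_matches_brute_force_enumeration_with_tie(self):
        scores = np.array([0.1, 0.4, 0.4, 0.9, 0.2, 0.4, 0.6, 0.8])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        wins = 0.0
        for sc in scores[y == 1]:
            for sh in scores[y == 0]:
                wins += 1.0 if sc > sh else (0.5 if sc == sh else 0.0)
        assert c_statistic(scores, y) == pytest.approx(wins / 16, rel=1e-12)

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-scores))).astype(int)
        assert c_statistic(scores, y) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        a = c_statistic(scores, y)
        b = c_statistic(np.exp(scores), y)
        assert a == pytest.approx(b, rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            c_statistic([1.0, 2.0], [1, 1])


class TestRiskBinDiagram:
    def test_two_bin_bayes_arithmetic(self):
        case = np.array([0.0] * 30 + [1.0] * 10)
        ctrl = np.array([0.0] * 10 + [1.0] * 30)
        t = risk_bin_diagram(case, ctrl, n_bins=2, prior=0.5)
        np.testing.assert_allclose(t.posterior_risk, [0.75, 0.25])

    def test_total_probability_conservation(self):
        rng = np.random.default_rng(4)
        case = rng.normal(1.0, 1.0, 400)
        ctrl = rng.normal(0.0, 1.0, 600)
        t = risk_bin_diagram(case, ctrl, n_bins=12)
        pi = t.prior
        p_bin = (t.count_case + t.count_control) / (
            t.count_case.sum() + t.count_control.sum()
        )
        # law of total probability holds when the prior is the case fraction
        mask = np.isfinite(t.posterior_risk)
        assert np.nansum(p_bin[mask] * t.posterior_risk[mask]) == pytest.approx(
            pi, abs=1e-12
        )
        assert t.count_case.sum() == 400 and t.count_control.sum() == 600

    def test_identical_distributions_posterior_near_prior(self):
        rng = np.random.default_rng(5)
        case = rng.normal(size=4000)
        ctrl = rng.normal(size=4000)
        t = risk_bin_diagram(case, ctrl, n_bins=6, prior=0.5)
        occupied = (t.count_case + t.count_control) >= 100
        assert np.all(np.abs(t.posterior_risk[occupied] - 0.5) < 0.15)

    def test_separated_distributions_hit_extremes(self):
        case = np.linspace(10, 11, 50)
        ctrl = np.linspace(0, 1, 50)
        t = risk_bin_diagram(case, ctrl, n_bins=12, prior=0.5)
        finite = t.posterior_risk[np.isfinite(t.posterior_risk)]
        assert finite[0] == pytest.approx(0.0, abs=1e-12)
        assert finite[-1] == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_range_single_bin(self):
        t = risk_bin_diagram([1.0] * 5, [1.0] * 5, n_bins=12)
        assert t.n_bins == 1
        assert t.posterior_risk[0] == pytest.approx(0.5)

    def test_equal_frequency_mode_counts_balanced(self):
        rng = np.random.default_rng(6)
        case = rng.normal(size=600)
        ctrl = rng.normal(size=600)
        t = risk_bin_diagram(case, ctrl, n_bins=6, equal_frequency=True)
        totals = t.count_case + t.count_control
        assert totals.min() > 100  # quantile bins are roughly balanced
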