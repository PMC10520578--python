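"""Weighted pooled logistic regression, marginal standardisation and PAF."""

import numpy as np
import pytest

from msmediate.outcome import (
    FitResult,
    RankDeficiencyError,
    SeparationError,
    marginal_standardise,
    paf,
    predict_proba,
    weighted_logistic,
)


def _expand_2x2(n11, n10, n01, n00):
    """Rows for a 2x2 exposure/outcome table: (a=1,y=1), (1,0), (0,1), (0,0)."""
    a = np.repeat([1.0, 1.0, 0.0, 0.0], [n11, n10, n01, n00])
    y = np.repeat([1.0, 0.0, 1.0, 0.0], [n11, n10, n01, n00])
    X = np.column_stack([np.ones_like(a), a])
    return X, y


class TestWeightedLogistic:
    def test_saturated_2x2_equals_cross_product_odds_ratio(self):
        n11, n10, n01, n00 = 37, 63, 25, 120
        X, y = _expand_2x2(n11, n10, n01, n00)
        fit = weighted_logistic(X, y, names=["const", "a"])
        hand_log_or = np.log((n11 * n00) / (n10 * n01))
        assert fit.params[1] == pytest.approx(hand_log_or, abs=1e-6)
        assert fit.params[0] == pytest.approx(np.log(n01 / n00), abs=1e-6)
        assert fit.converged

    def test_agrees_with_likelihood_grid_search(self):
        """Two-stage exhaustive grid search over (b0, b1) as an independent
        maximiser; agreement to 3 decimals on a one-covariate toy."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        X = np.column_stack([np.ones_like(x), x])
        fit = weighted_logistic(X, y, names=["const", "x"])

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return np.sum(y * eta - np.log1p(np.exp(eta)))

        centre = (0.0, 0.0)
        width = 3.0
        for _ in range(4):  # zoom the grid: 3.0 -> 0.003 spacing overall
            b0s = np.linspace(centre[0] - width, centre[0] + width, 61)
            b1s = np.linspace(centre[1] - width, centre[1] + width, 61)
            vals = np.array([[loglik(b0, b1) for b1 in b1s] for b0 in b0s])
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            centre = (b0s[i], b1s[j])
            width /= 10
        assert fit.params[0] == pytest.approx(centre[0], abs=1e-3)
        assert fit.params[1] == pytest.approx(centre[1], abs=1e-3)

    def test_weight_rescaling_leaves_fit_unchanged(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(300), rng.normal(size=300)])
        y = (rng.random(300) < 0.4).astype(float)
        w = rng.uniform(0.5, 2.0, 300)
        f1 = weighted_logistic(X, y, w)
        f2 = weighted_logistic(X, y, 2.0 * w)
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-9)

    def test_weights_reproduce_frequency_expansion(self):
        """Integer weights are equivalent to repeating rows."""
        X, y = _expand_2x2(5, 9, 4, 11)
        Xu = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
        yu = np.array([1.0, 0.0, 1.0, 0.0])
        wu = np.array([5.0, 9.0, 4.0, 11.0])
        f_rows = weighted_logistic(X, y)
        f_w = weighted_logistic(Xu, yu, wu)
        np.testing.assert_allclose(f_rows.params, f_w.params, atol=1e-8)

    def test_constant_outcome_is_separation(self):
        X = np.ones((50, 1))
        with pytest.raises(SeparationError):
            weighted_logistic(X, np.zeros(50))

    def test_perfect_separation_detected(self):
        x = np.concatenate([-np.ones(30), np.ones(30)])
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones_like(x), x])
        with pytest.raises(SeparationError):
            weighted_logistic(X, y, names=["const", "x"])

    def test_rank_deficiency_names_aliased_column(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        X = np.column_stack([np.ones(100), x, 2.0 * x])
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(RankDeficiencyError, match=r"aliased columns: \['x2?'\]"):
            weighted_logistic(X, y, names=["const", "x", "x2"])

    def test_nonpositive_weights_rejected(self):
        X = np.ones((10, 1))
        y = np.tile([0.0, 1.0], 5)
        with pytest.raises(ValueError):
            weighted_logistic(X, y, np.zeros(10))


class TestMarginalStandardise:
    def test_null_exposure_coefficient_gives_null_contrast(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(200), (rng.random(200) < 0.5).astype(float), rng.normal(size=200)])
        fit = FitResult(np.array([-1.0, 0.0, 0.5]), ["const", "a", "x"], True, 1, 0.0, 0.0)
        est = marginal_standardise(fit, X, "a")
        assert est.odds_ratio == pytest.approx(1.0)
        assert est.risk_difference_pp == pytest.approx(0.0)

    def test_matches_hand_evaluated_logistic_predictions(self):
        """Explicit per-row computation of the standardised risks."""
        X = np.array(
            [
                [1.0, 1.0, 0.2],
                [1.0, 0.0, -1.0],
                [1.0, 0.0, 0.5],
                [1.0, 1.0, 1.5],
            ]
        )
        beta = np.array([-0.4, 0.9, -0.6])
        fit = FitResult(beta, ["const", "a", "x"], True, 1, 0.0, 0.0)
        w = np.array([1.0, 2.0, 1.5, 0.5])
        est = marginal_standardise(fit, X, "a", w)
        r1 = r0 = 0.0
        for row, wi in zip(X, w):
            lp1 = beta[0] + beta[1] * 1.0 + beta[2] * row[2]
            lp0 = beta[0] + beta[2] * row[2]
            r1 += wi / (1 + np.exp(-lp1))
            r0 += wi / (1 + np.exp(-lp0))
        r1 /= w.sum()
        r0 /= w.sum()
        assert est.risk_exposed == pytest.approx(r1, abs=1e-8)
        assert est.risk_unexposed == pytest.approx(r0, abs=1e-8)
        assert est.risk_difference_pp == pytest.approx(100 * (r1 - r0), abs=1e-8)
        assert est.odds_ratio == pytest.approx((r1 / (1 - r1)) / (r0 / (1 - r0)), abs=1e-10)

    def test_risks_bounded_by_fitted_probabilities(self):
        rng = np.random.default_rng(9)
        n = 500
        X = np.column_stack([np.ones(n), (rng.random(n) < 0.3).astype(float), rng.normal(size=n)])
        y = (rng.random(n) < 0.35).astype(float)
        fit = weighted_logistic(X, y, names=["const", "a", "x"])
        est = marginal_standardise(fit, X, "a")
        X1, X0 = X.copy(), X.copy()
        X1[:, 1], X0[:, 1] = 1.0, 0.0
        p_all = np.concatenate([predict_proba(fit, X1), predict_proba(fit, X0)])
        for r in (est.risk_exposed, est.risk_unexposed):
            assert p_all.min() <= r <= p_all.max()

    def test_unknown_exposure_rejected(self):
        fit = FitResult(np.zeros(2), ["const", "a"], True, 1, 0.0, 0.0)
        with pytest.raises(ValueError):
            marginal_standardise(fit, np.ones((5, 2)), "b")


class TestPAF:
    @pytest.mark.parametrize(
        "total,unexposed,expected",
        [(0.20, 0.20, 0.0), (0.20, 0.18, 10.0), (0.18, 0.20, -100 * 2 / 18)],
    )
    def test_printed_formula(self, total, unexposed, expected):
        assert paf(total, unexposed) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_total_prevalence(self):
        vals = [paf(t, 0.15) for t in np.linspace(0.16, 0.4, 10)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            paf(0.0, 0.1)


class TestDoubleRobustness:
    def test_single_model_misspecification_still_near_truth(self):
        """Dropping a strong confounder (lagged caseness) from either the
        weight model or the outcome model barely moves the TE estimate,
        while the naive unadjusted contrast is grossly biased; each
        single-misspecification bias stays below a quarter of the naive
        bias."""
        from msmediate import MediationMSM, SimParams
        from msmediate.design import build_design
        from msmediate.preprocess import VariableRoles
        from msmediate.simulate import oracle_effects
        from msmediate.weighting import fit_exposure_weights

        truth = oracle_effects(SimParams(), n_mc=100_000, seed=1).oracle_TE_rd
        roles = VariableRoles()
        table = MediationMSM.from_simulation(
            SimParams(n_individuals=8000, seed=303)
        ).analysis_table
        y = table["caseness"].to_numpy(float)

        dm_naive = build_design(table, ["unemployed"])
        naive_fit = weighted_logistic(dm_naive.X, y, names=dm_naive.names, check_rank=False)
        naive = marginal_standardise(naive_fit, dm_naive.X, "unemployed").risk_difference_pp

        # weights missing the confounder, outcome model correct
        roles_bad_w = roles.replace(
            extra_lags=("unemployed_lag", "mcs_lag", "log_income_lag")
        )
        ws_bad = fit_exposure_weights(table, roles_bad_w)
        dm_full = build_design(table, ["unemployed"] + list(roles.adjustment_set))
        fit1 = weighted_logistic(dm_full.X, y, ws_bad.w, names=dm_full.names, check_rank=False)
        est1 = marginal_standardise(fit1, dm_full.X, "unemployed", ws_bad.w).risk_difference_pp

        # weights correct, outcome model missing the confounder
        ws_ok = fit_exposure_weights(table, roles)
        dm_bad = build_design(
            table,
            ["unemployed"] + [c for c in roles.adjustment_set if c != "caseness_lag"],
        )
        fit2 = weighted_logistic(dm_bad.X, y, ws_ok.w, names=dm_bad.names, check_rank=False)
        est2 = marginal_standardise(fit2, dm_bad.X, "unemployed", ws_ok.w).risk_difference_pp

        naive_bias = abs(naive - truth)
        assert naive_bias > 3.0  # the confounding is real
        assert abs(est1 - truth) < 0.25 * naive_bias
        assert abs(est2 - truth) < 0.25 * naive_bias


class TestAgainstReferenceImplementation:
    def test_matches_statsmodels_weighted_glm(self):
        """Independent route: statsmodels GLM with frequency weights."""
        import statsmodels.api as sm

        rng = np.random.default_rng(14)
        n = 2000
        X = np.column_stack(
            [np.ones(n), (rng.random(n) < 0.3).astype(float), rng.normal(size=n),
             rng.normal(size=n)]
        )
        eta = -0.5 + 0.7 * X[:, 1] - 0.4 * X[:, 2] + 0.2 * X[:, 3]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        w = rng.uniform(0.3, 3.0, n)
        ours = weighted_logistic(X, y, w)
        ref = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)
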