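"""Stabilised weights, mediator density ratios and SMD balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msmediate import SimParams, generate_panel
from msmediate.preprocess import VariableRoles, build_analysis_table, derive_analysis_variables
from msmediate.weighting import (
    WeightSet,
    balance_report,
    fit_exposure_weights,
    fit_mediator_weights,
    smd,
    truncate_weights,
)

#: Minimal roles for hand-computable worlds: one binary confounder ``z``
#: treated as a lagged covariate, so the mediator-weight numerator (exposure
#: only) and denominator (exposure + z) genuinely differ.
TOY_ROLES = VariableRoles(
    exposure="a",
    outcome="y",
    mediator_continuous="m",
    mediator_binary="pov",
    baseline=(),
    age_terms=(),
    time_varying=(),
    region=None,
    extra_lags=("z",),
    id_col="pid",
)


def _toy_confounded(n=40_000, seed=0):
    """A depends on Z with known probabilities: P(A=1|Z=1)=0.6, P(A=1|Z=0)=0.2."""
    rng = np.random.default_rng(seed)
    z = (rng.random(n) < 0.5).astype(float)
    pa = np.where(z == 1, 0.6, 0.2)
    a = (rng.random(n) < pa).astype(float)
    m = 0.8 * z + rng.normal(0, 1.0, n)
    y = (rng.random(n) < 0.3).astype(float)
    return pd.DataFrame(
        {"pid": np.arange(n), "a": a, "z": z, "m": m, "pov": 0.0, "y": y}
    )


class TestExposureWeights:
    def test_stratum_weights_match_closed_form(self):
        """Stabilised weights equal P-hat(a) / P-hat(a|z), computable by hand
        from the 2x2 table because the saturated logistic MLE reproduces the
        empirical stratum rates."""
        df = _toy_confounded()
        ws = fit_exposure_weights(df, TOY_ROLES)
        p_marg = df["a"].mean()
        for z in (0.0, 1.0):
            for a in (0.0, 1.0):
                sel = (df["z"] == z) & (df["a"] == a)
                p_cond = df.loc[df["z"] == z, "a"].mean()
                expected = (p_marg if a == 1 else 1 - p_marg) / (
                    p_cond if a == 1 else 1 - p_cond
                )
                np.testing.assert_allclose(ws.w[sel.to_numpy()], expected, rtol=1e-6)

    def test_randomised_exposure_gives_unit_weights(self):
        rng = np.random.default_rng(4)
        n = 20_000
        df = pd.DataFrame(
            {
                "pid": np.arange(n),
                "a": (rng.random(n) < 0.4).astype(float),
                "z": rng.normal(size=n),
                "m": rng.normal(size=n),
                "pov": 0.0,
                "y": 0.0,
            }
        )
        ws = fit_exposure_weights(df, TOY_ROLES)
        assert abs(ws.w.mean() - 1.0) < 0.02
        assert ws.w.std() < 0.05

    def test_mean_weight_near_one_on_default_simulation(self, mid_table):
        ws = fit_exposure_weights(mid_table)
        assert 0.9 <= ws.w.mean() <= 1.1


class TestMediatorWeights:
    def test_gaussian_ratio_matches_hand_computation(self):
        """With one confounder shifting the mediator mean, sw_M equals the
        ratio of the two fitted normal densities, reproduced here with
        independent OLS fits (numpy lstsq on explicitly built designs)."""
        df = _toy_confounded(n=20_000, seed=1)
        ws = fit_mediator_weights(df, TOY_ROLES)
        m, a, z = (df[c].to_numpy() for c in ("m", "a", "z"))
        ones = np.ones_like(m)

        def dens(X):
            beta, *_ = np.linalg.lstsq(X, m, rcond=None)
            r = m - X @ beta
            s = np.sqrt(r @ r / (len(m) - X.shape[1]))
            return np.exp(-0.5 * (r / s) ** 2) / s

        expected = dens(np.column_stack([ones, a])) / dens(np.column_stack([ones, a, z]))
        np.testing.assert_allclose(ws.sw_M, expected, rtol=1e-8)

    def test_independent_mediator_gives_unit_weights(self):
        rng = np.random.default_rng(7)
        n = 20_000
        df = pd.DataFrame(
            {
                "pid": np.arange(n),
                "a": (rng.random(n) < 0.4).astype(float),
                "z": rng.normal(size=n),
                "m": rng.normal(size=n),  # independent of z given a
                "pov": 0.0,
                "y": 0.0,
            }
        )
        ws = fit_mediator_weights(df, TOY_ROLES)
        assert abs(ws.sw_M.mean() - 1.0) < 0.02
        assert np.percentile(np.abs(ws.sw_M - 1.0), 95) < 0.1

    def test_combined_weight_mean_on_default_simulation(self, mid_table):
        ws = fit_mediator_weights(mid_table)
        assert 0.8 <= ws.w.mean() <= 1.2

    def test_degenerate_density_rejected(self):
        df = _toy_confounded(n=500, seed=2)
        df["m"] = 2.0 * df["z"]  # deterministic given the denominator model
        with pytest.raises(ValueError, match="degenerate"):
            fit_mediator_weights(df, TOY_ROLES)


class TestTruncation:
    def test_equal_weights_unchanged(self):
        ws = WeightSet(sw_A=np.ones(100))
        out = truncate_weights(ws)
        np.testing.assert_array_equal(out.w, ws.w)
        assert out.fraction_truncated == 0.0

    def test_extreme_weight_clipped_to_percentile(self):
        w = np.ones(1000)
        w[0] = 1e6
        expected_hi = np.percentile(w, 99)
        out = truncate_weights(WeightSet(sw_A=w), 1, 99)
        assert out.w.max() == pytest.approx(expected_hi)
        assert out.fraction_truncated == pytest.approx(1 / 1000)

    def test_bad_percentiles_rejected(self):
        with pytest.raises(ValueError):
            truncate_weights(WeightSet(sw_A=np.ones(10)), 60, 40)

    def test_cde_truncation_preserves_product(self):
        rng = np.random.default_rng(0)
        ws = WeightSet(sw_A=rng.uniform(0.5, 2, 500), sw_M=rng.lognormal(0, 1, 500))
        out = truncate_weights(ws, 1, 99)
        lo, hi = out.truncation
        np.testing.assert_allclose(out.w, np.clip(ws.w, lo, hi))


class TestSMD:
    def test_identical_groups_zero(self):
        x = np.tile([1.0, 2.0, 3.0], 2)
        g = np.repeat([0, 1], 3)
        assert smd(x, g) == 0.0

    def test_hand_computed_value(self):
        # group1 {2,4}: mean 3, var 1; group0 {0,2}: mean 1, var 1 -> SMD 2
        x = np.array([2.0, 4.0, 0.0, 2.0])
        g = np.array([1, 1, 0, 0])
        assert smd(x, g) == pytest.approx(2.0)

    def test_binary_uses_proportion_variance(self):
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        g = np.array([1, 1, 1, 0, 0, 0])
        p1, p0 = 2 / 3, 1 / 3
        expected = abs(p1 - p0) / np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2)
        assert smd(x, g) == pytest.approx(expected)

    def test_zero_variance_unequal_means_is_infinite(self):
        x = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([1, 1, 0, 0])
        assert smd(x, g) == np.inf

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.floats(-50, 50).map(lambda v: round(v, 6)), min_size=4, max_size=30),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_symmetry_and_affine_invariance(self, vals, scale, shift):
        vals = np.asarray(vals)
        g = np.arange(len(vals)) % 2
        base = smd(vals, g)
        assert smd(vals, 1 - g) == pytest.approx(base, rel=1e-9, abs=1e-12)
        assert smd(scale * vals + shift, g) == pytest.approx(base, rel=1e-6, abs=1e-9)


class TestBalance:
    def test_confounded_simulation_balances_after_weighting(self, mid_table):
        """Planted confounding: at least one covariate grossly imbalanced
        before weighting (lagged exposure the worst), all below 0.1 after."""
        ws = fit_exposure_weights(mid_table)
        rep = balance_report(mid_table, VariableRoles(), ws)
        worst = rep.table.sort_values("smd_pre", ascending=False).iloc[0]
        assert worst["covariate"] == "unemployed_lag"
        assert worst["smd_pre"] > 0.2
        assert rep.max_post < 0.1
        assert rep.all_balanced()

    def test_weighting_randomised_exposure_does_no_harm(self):
        """On exchangeable data every SMD is already small and weighting
        moves none of them by more than 0.05."""
        params = SimParams(
            n_individuals=2500,
            seed=31,
            emp_persist=0.0,
            emp_caseness_lag=0.0,
            emp_log_income_lag=0.0,
            emp_benefits_lag=0.0,
            emp_renter_lag=0.0,
            emp_educ_med=0.0,
            emp_educ_low=0.0,
            emp_female=0.0,
            emp_age=0.0,
            emp_pcs_lag=0.0,
            emp_intercept=1.06,
            emp_intercept_wave1=1.06,
        )
        table = build_analysis_table(derive_analysis_variables(generate_panel(params)))
        ws = fit_exposure_weights(table)
        rep = balance_report(table, VariableRoles(), ws)
        assert rep.table["smd_pre"].max() < 0.1
        # no harm: weighting never worsens any covariate's balance materially
        assert (rep.table["smd_post"] - rep.table["smd_pre"]).max() < 0.05
        assert rep.max_post < 0.1

    def test_two_stratum_weighted_prevalence_equals_direct_standardisation(self):
        """In a discrete world the IPTW-weighted outcome prevalence by
        exposure equals the stratification estimate computed by hand."""
        rng = np.random.default_rng(3)
        n = 60_000
        z = (rng.random(n) < 0.5).astype(float)
        a = (rng.random(n) < np.where(z == 1, 0.7, 0.3)).astype(float)
        py = 0.2 + 0.3 * a + 0.2 * z
        y = (rng.random(n) < py).astype(float)
        df = pd.DataFrame({"pid": np.arange(n), "a": a, "z": z, "m": rng.normal(size=n), "pov": 0.0, "y": y})
        ws = fit_exposure_weights(df, TOY_ROLES)
        w = ws.w
        # brute-force direct standardisation over the z strata
        for aa in (0.0, 1.0):
            direct = sum(
                y[(a == aa) & (z == zz)].mean() * (z == zz).mean() for zz in (0.0, 1.0)
            )
            weighted = np.sum(w[a == aa] * y[a == aa]) / np.sum(w[a == aa])
            assert weighted == pytest.approx(direct, abs=0.01)
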