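"""Percentage mediation, cluster bootstrap, transitions and strata."""

import numpy as np
import pandas as pd
import pytest

from msmediate import MediationMSM, SimParams
from msmediate.impute import ImputationSet, ImputationSpec
from msmediate.mediation import (
    bootstrap_interval,
    estimate_effect,
    estimate_single,
    percent_mediation,
    transition_table,
)


class TestPercentMediation:
    @pytest.mark.parametrize(
        "te,cde,expected",
        [
            (7.09, 6.08, 100 * (7.09 - 6.08) / 7.09),   # headline analysis
            (7.42, 6.30, 100 * (7.42 - 6.30) / 7.42),   # job-loss transition
            (5.0, 5.0, 0.0),
            (-6.35, -5.79, 100 * (-6.35 + 5.79) / -6.35),
        ],
    )
    def test_attenuation_formula(self, te, cde, expected):
        assert percent_mediation(te, cde) == pytest.approx(expected, rel=1e-12)

    def test_can_exceed_bounds(self):
        assert percent_mediation(2.0, -1.0) == pytest.approx(150.0)
        assert percent_mediation(2.0, 3.0) == pytest.approx(-50.0)

    def test_null_total_effect_undefined(self):
        with pytest.raises(ValueError):
            percent_mediation(0.0, 1.0)


class TestBootstrapInterval:
    def test_constant_estimator_has_zero_width(self, analysis_table):
        out = bootstrap_interval(
            analysis_table.head(200), lambda df: 3.14, n_boot=50, seed=1
        )
        assert out.se == pytest.approx(0.0, abs=1e-12)
        assert out.ci_normal[0] == pytest.approx(out.ci_normal[1], abs=1e-10)
        assert out.ci_normal[0] == pytest.approx(3.14)

    def test_sample_mean_se_matches_sampling_theory(self):
        """Cluster bootstrap of the mean of n i.i.d. normals (one row per
        person) reproduces sigma/sqrt(n) within 15%."""
        rng = np.random.default_rng(12)
        n, sigma = 400, 2.0
        df = pd.DataFrame({"pid": np.arange(n), "x": rng.normal(0, sigma, n)})
        out = bootstrap_interval(df, lambda d: d["x"].mean(), n_boot=1000, seed=5)
        assert out.se == pytest.approx(sigma / np.sqrt(n), rel=0.15)

    def test_interval_symmetric_about_point(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"pid": np.arange(150), "x": rng.normal(size=150)})
        point = df["x"].mean()
        out = bootstrap_interval(df, lambda d: d["x"].mean(), n_boot=200, seed=3, point=point)
        lo, hi = out.ci_normal
        assert hi - point == pytest.approx(point - lo, abs=1e-12)

    def test_undefined_replicates_counted_and_warned(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"pid": np.arange(50), "x": rng.normal(size=50)})

        def flaky(d):
            return d["x"].mean() if d["x"].mean() > -0.05 else float("nan")

        with pytest.warns(UserWarning, match="undefined"):
            bootstrap_interval(df, flaky, n_boot=100, seed=11)


class TestTransitions:
    @pytest.fixture()
    def four_person_table(self):
        # unemployed/unemployed_lag patterns chosen so the at-risk sets are
        # enumerable by hand
        rows = [
            # pid, wave, unemployed, unemployed_lag
            (1, 2, 0.0, 0.0),  # stays employed      -> loss-risk set
            (1, 3, 1.0, 0.0),  # loses job           -> loss-risk set
            (2, 2, 1.0, 1.0),  # stays unemployed    -> gain-risk set
            (2, 3, 0.0, 1.0),  # gains job           -> gain-risk set
            (3, 2, 0.0, 0.0),  # always employed     -> loss-risk set
            (3, 3, 0.0, 0.0),
            (4, 2, 1.0, 0.0),  # loss at wave 2      -> loss-risk set
            (4, 3, 1.0, 1.0),  # then stays out      -> gain-risk set
        ]
        return pd.DataFrame(
            rows, columns=["pid", "wave", "unemployed", "unemployed_lag"]
        )

    def test_at_risk_rows_match_manual_enumeration(self, four_person_table):
        gain = transition_table(four_person_table, "gain")
        loss = transition_table(four_person_table, "loss")
        assert len(gain) == 3 and len(loss) == 5
        assert gain["transition"].tolist() == [0.0, 1.0, 0.0]
        assert loss["transition"].tolist() == [0.0, 1.0, 0.0, 0.0, 1.0]

    def test_gain_and_loss_sets_are_disjoint_and_exhaustive(self, four_person_table):
        gain = transition_table(four_person_table, "gain")
        loss = transition_table(four_person_table, "loss")
        gkeys = set(map(tuple, gain[["pid", "wave"]].to_numpy()))
        lkeys = set(map(tuple, loss[["pid", "wave"]].to_numpy()))
        assert not gkeys & lkeys
        assert len(gkeys) + len(lkeys) == len(four_person_table)

    def test_always_employed_person_only_at_risk_of_loss(self, four_person_table):
        gain = transition_table(four_person_table, "gain")
        loss = transition_table(four_person_table, "loss")
        assert 3 not in gain["pid"].to_numpy()
        assert (loss["pid"] == 3).sum() == 2

    def test_unknown_direction_rejected(self, four_person_table):
        with pytest.raises(ValueError):
            transition_table(four_person_table, "sideways")


class TestEstimateEffect:
    def test_single_dataset_pooling_identity(self, mid_table):
        """m identical completed datasets pool to exactly the single-dataset
        estimate."""
        single = estimate_single(mid_table)
        imp = ImputationSet(datasets=[mid_table, mid_table], spec=ImputationSpec(m=2))
        pooled = estimate_effect(imp)
        assert pooled["te"].risk_difference_pp == pytest.approx(
            single["te"].risk_difference_pp, abs=1e-12
        )
        assert pooled["cde"].odds_ratio == pytest.approx(
            single["cde"].odds_ratio, abs=1e-12
        )

    def test_no_mediated_path_means_te_close_to_cde(self):
        """With the income pathway switched off, TE and CDE agree within
        twice the bootstrap s.e. of their difference."""
        p = SimParams(n_individuals=4000, seed=61, beta_M=0.0)
        model = MediationMSM.from_simulation(p)
        res = model.fit(n_boot=100, seed=61, truncate=(1.0, 99.0))
        reps = res._result._replicates
        diff_se = float(np.std(reps["rd_te"] - reps["rd_cde"], ddof=1))
        assert abs(res.te.risk_difference_pp - res.cde.risk_difference_pp) < 2 * diff_se


class TestStratified:
    def test_strata_partition_the_sample(self):
        model = MediationMSM.from_simulation(SimParams(n_individuals=1500, seed=77))
        strat = model.fit_stratified("gender", n_boot=1, m=1, seed=77)
        total = sum(r.te.n_observations for r in strat.values())
        assert total == model.nobs
        assert set(strat) == {"men", "women"}

    def test_small_stratum_skipped_with_warning(self):
        model = MediationMSM.from_simulation(SimParams(n_individuals=300, seed=78))
        with pytest.warns(UserWarning, match="skipped"):
            strat = model.fit_stratified(
                "gender", n_boot=1, m=1, seed=78, min_stratum_persons=10_000
            )
        assert strat == {}

    def test_planted_age_interaction_orders_strata(self):
        """A mediated pathway four times stronger for ages 41-64 shows up as
        clearly larger percentage mediation in the older stratum."""
        p = SimParams(n_individuals=8000, seed=55, beta_M_older_scale=4.0)
        model = MediationMSM.from_simulation(p)
        strat = model.fit_stratified(
            "age-band", n_boot=1, m=1, seed=55, truncate=(1.0, 99.0)
        )
        assert strat["41-64"].pct_mediation > strat["25-40"].pct_mediation + 5.0


class TestBootstrapScaling:
    def test_interval_width_shrinks_like_root_n(self):
        """The bootstrap CI width for the TE risk difference scales roughly
        as 1/sqrt(n) across a fourfold range of sample sizes."""
        widths = {}
        for n in (1000, 4000):
            model = MediationMSM.from_simulation(SimParams(n_individuals=n, seed=202))
            res = model.fit(n_boot=120, seed=202, truncate=(1.0, 99.0))
            lo, hi = res.te.rd_ci
            widths[n] = hi - lo
        ratio = widths[1000] / widths[4000]
        assert 2.0 * 0.6 < ratio < 2.0 * 1.6  # expect ~sqrt(4) = 2
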