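"""Model/Results interface for the marginal structural mediation analysis.

:class:`MediationMSM` is constructed from a long person-by-wave panel (or
directly from simulation parameters), prepares the lagged analysis table,
and :meth:`MediationMSM.fit` runs the full double-robust analysis: multiple
imputation (or complete-case), stabilised exposure and mediator weights,
weighted pooled logistic outcome models, marginal standardisation, and a
person-level bootstrap.  The returned :class:`MediationResults` carries the
total effect, controlled direct effect, percentage mediation, population
attributable fractions, balance diagnostics and a printable summary table.

Example
-------
>>> from msmediate import SimParams, MediationMSM
>>> model = MediationMSM.from_simulation(SimParams(n_individuals=2000, seed=7))
>>> res = model.fit(n_boot=200, seed=7)
>>> print(res.summary())           # doctest: +SKIP
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .impute import ImputationSpec, drop_high_missingness, mice
from .mediation import (
    Z975,
    AnalysisConfig,
    EffectEstimate,
    MediationResult,
    _Engine,
    _pool_marginals,
    percent_mediation,
    refresh_derived_columns,
    stratified_run,
    transition_roles,
    transition_table,
)
from .preprocess import (
    VariableRoles,
    build_analysis_table,
    derive_analysis_variables,
    restrict_sample,
)
from .simulate import SimParams, generate_panel, inject_missingness
from .weighting import balance_report

__all__ = ["MediationMSM", "MediationResults"]


def _attach_interval(est: EffectEstimate, reps: dict[str, np.ndarray]) -> None:
    key = est.mode.lower()

    def ci(name, point):
        r = reps[f"{name}_{key}"]
        se = float(np.std(r, ddof=1))
        return (point - Z975 * se, point + Z975 * se)

    est.or_ci = ci("or", est.odds_ratio)
    est.rd_ci = ci("rd", est.risk_difference_pp)
    est.prevalence_unexposed_ci = ci("prev0", est.prevalence_unexposed_pp)


def _run_mediation(
    table: pd.DataFrame,
    config: AnalysisConfig,
    roles: VariableRoles | None = None,
) -> MediationResult:
    """Point estimation plus cluster bootstrap on one analysis table.

    ``table`` is a lagged analysis table that may still contain missing
    values.  With missingness, the point estimate pools ``config.m``
    imputations while each bootstrap replicate re-imputes once (m = 1)
    after resampling persons; on complete data the bootstrap reuses the
    prebuilt design matrices with warm-started Newton refits.
    """
    roles = roles or VariableRoles()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 33717]))

    raw_cols = [
        c for c in set(
            list(roles.drop_rule_variables)
            + ["employed", "income", "ghq", "mcs_lag", "income_lag", "employed_lag"]
        ) if c in table.columns
    ]
    has_missing = table[raw_cols].isna().any().any() if raw_cols else False

    if config.complete_case and has_missing:
        table = table.dropna(subset=[c for c in raw_cols]).reset_index(drop=True)
        has_missing = False

    if has_missing:
        kept = drop_high_missingness(table, variables=roles.drop_rule_variables)
        spec = ImputationSpec(
            m=config.m,
            n_chain_iterations=config.chain_iterations,
            seed=int(rng.integers(2**31 - 1)),
        )
        imp = mice(kept, spec)
        completed = [refresh_derived_columns(d, d.attrs.get("poverty_line")) for d in imp.datasets]
        engines = [_Engine(d, roles, config.truncate) for d in completed]
        results = [e.estimate(store_warm=True) for e in engines]
        n_ind = completed[0][roles.id_col].nunique()
        n_obs = len(completed[0])
        pre_boot_table = kept
    else:
        completed = [refresh_derived_columns(table, table.attrs.get("poverty_line"))]
        engines = [_Engine(completed[0], roles, config.truncate)]
        results = [engines[0].estimate(store_warm=True)]
        n_ind = completed[0][roles.id_col].nunique()
        n_obs = len(completed[0])
        pre_boot_table = completed[0]

    te = _pool_marginals(results, "te", n_ind, n_obs)
    cde = _pool_marginals(results, "cde", n_ind, n_obs)
    pct = percent_mediation(te.risk_difference_pp, cde.risk_difference_pp)

    # ---- cluster bootstrap ------------------------------------------------
    reps: dict[str, list[float]] = {
        k: [] for k in ("rd_te", "rd_cde", "or_te", "or_cde", "prev0_te", "prev0_cde", "pct")
    }
    n_failed = 0
    engine0 = engines[0]
    for _ in range(config.n_boot):
        try:
            if has_missing:
                persons = pre_boot_table[roles.id_col].unique()
                pick = rng.choice(persons, size=len(persons), replace=True)
                groups = pre_boot_table.groupby(roles.id_col).indices
                row_idx = np.concatenate([groups[p] for p in pick])
                sub = pre_boot_table.iloc[row_idx].reset_index(drop=True)
                sub.attrs.update(pre_boot_table.attrs)
                # resampled duplicates become distinct pseudo-persons
                lengths = [len(groups[p]) for p in pick]
                sub[roles.id_col] = np.repeat(np.arange(len(pick)), lengths)
                spec_b = ImputationSpec(
                    m=1,
                    n_chain_iterations=config.chain_iterations_boot,
                    seed=int(rng.integers(2**31 - 1)),
                )
                # short replicate chains trip the drift diagnostic by design
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    comp = refresh_derived_columns(
                        mice(sub, spec_b).datasets[0], sub.attrs.get("poverty_line")
                    )
                r = _Engine(comp, roles, config.truncate).estimate()
            else:
                rows = engine0.bootstrap_rows(rng)
                r = engine0.estimate(
                    rows, max_iter=config.boot_newton_steps, use_warm=True
                )
            rd_te, rd_cde = r["te"].risk_difference_pp, r["cde"].risk_difference_pp
            reps["rd_te"].append(rd_te)
            reps["rd_cde"].append(rd_cde)
            reps["or_te"].append(r["te"].odds_ratio)
            reps["or_cde"].append(r["cde"].odds_ratio)
            reps["prev0_te"].append(r["te"].prevalence_unexposed_pp)
            reps["prev0_cde"].append(r["cde"].prevalence_unexposed_pp)
            reps["pct"].append(percent_mediation(rd_te, rd_cde) if rd_te != 0 else np.nan)
        except Exception:
            n_failed += 1
    reps_arr = {k: np.asarray(v, dtype=float) for k, v in reps.items()}
    pct_reps = reps_arr["pct"]
    pct_ok = pct_reps[~np.isnan(pct_reps)]

    result = MediationResult(
        te=te,
        cde=cde,
        pct_mediation=pct,
        n_boot=config.n_boot,
        n_boot_failed=n_failed + int(np.isnan(pct_reps).sum()),
        seed=config.seed,
    )
    if len(pct_ok) >= 2:
        se = float(pct_ok.std(ddof=1))
        result.pct_mediation_ci = (pct - Z975 * se, pct + Z975 * se)
        result.pct_mediation_ci_percentile = tuple(np.percentile(pct_ok, [2.5, 97.5]))
        result.bootstrap_se = {
            k: float(np.std(v[~np.isnan(v)], ddof=1)) for k, v in reps_arr.items() if len(v) >= 2
        }
        _attach_interval(te, reps_arr)
        _attach_interval(cde, reps_arr)
    result._replicates = reps_arr  # kept for diagnostics/tests
    result._balance = {
        "te": balance_report(completed[0], roles, results[0]["weights_te"]),
        "cde": balance_report(completed[0], roles, results[0]["weights_cde"]),
    }
    return result


class MediationMSM:
    """Double-robust marginal structural mediation model.

    Parameters
    ----------
    panel :
        Long person-by-wave panel with the documented column dictionary
        (one row per person-wave; employment, income, GHQ-12 score and
        confounders).  Derived variables and the lagged analysis table are
        built on construction.
    roles :
        Column-to-role mapping; defaults match the synthetic panel.
    already_prepared :
        Set when ``panel`` is a ready-made lagged analysis table.
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        roles: VariableRoles | None = None,
        *,
        already_prepared: bool = False,
    ):
        self.roles = roles or VariableRoles()
        if already_prepared:
            self.analysis_table = panel
        else:
            prepared = restrict_sample(panel)
            prepared = derive_analysis_variables(prepared)
            self.analysis_table = build_analysis_table(prepared, self.roles)
        self.roles.validate_against(self.analysis_table)
        self.nobs = len(self.analysis_table)
        self.n_individuals = self.analysis_table[self.roles.id_col].nunique()

    @classmethod
    def from_dataframe(cls, panel: pd.DataFrame, roles: VariableRoles | None = None) -> "MediationMSM":
        return cls(panel, roles)

    @classmethod
    def from_csv(cls, path, roles: VariableRoles | None = None) -> "MediationMSM":
        panel = pd.read_csv(path)
        for col in ("educ", "region"):
            if col in panel.columns:
                panel[col] = panel[col].astype("category")
        return cls(panel, roles)

    @classmethod
    def from_simulation(
        cls, params: SimParams, *, missingness: bool = False, roles: VariableRoles | None = None
    ) -> "MediationMSM":
        panel = generate_panel(params)
        if missingness:
            panel = inject_missingness(panel, params)
        return cls(panel, roles)

    def fit(
        self,
        *,
        mode: str = "full",
        n_boot: int = 1000,
        m: int = 20,
        seed: int = 0,
        complete_case: bool = False,
        truncate: tuple[float, float] | None = None,
        config: AnalysisConfig | None = None,
    ) -> "MediationResults":
        """Estimate TE, CDE and percentage mediation with bootstrap CIs."""
        cfg = config or AnalysisConfig(
            mode=mode,
            n_boot=n_boot,
            m=m,
            seed=seed,
            complete_case=complete_case,
            truncate=truncate,
        )
        cfg.validate()
        if cfg.mode == "full":
            table, roles = self.analysis_table, self.roles
        else:
            direction = "gain" if cfg.mode == "transition-gain" else "loss"
            base = refresh_derived_columns(
                self.analysis_table, self.analysis_table.attrs.get("poverty_line")
            )
            table = transition_table(base, direction)
            roles = transition_roles(self.roles)
        res = _run_mediation(table, cfg, roles)
        return MediationResults(self, res, cfg, roles)

    def fit_stratified(self, strata: str, *, n_boot: int = 1000, m: int = 20, seed: int = 0,
                       min_stratum_persons: int = 100, **kw) -> dict[str, "MediationResults"]:
        """Per-stratum analyses (gender, education, age-band or poverty)."""
        cfg = AnalysisConfig(
            strata=strata, n_boot=n_boot, m=m, seed=seed,
            min_stratum_persons=min_stratum_persons, **kw,
        )
        cfg.validate()
        base = refresh_derived_columns(
            self.analysis_table, self.analysis_table.attrs.get("poverty_line")
        )
        raw = stratified_run(base, cfg, self.roles)
        return {k: MediationResults(self, v, cfg, self.roles) for k, v in raw.items()}


class MediationResults:
    """Results container with a Table-1-style summary."""

    def __init__(self, model: MediationMSM, result: MediationResult, config: AnalysisConfig,
                 roles: VariableRoles):
        self.model = model
        self._result = result
        self.config = config
        self.roles = roles

    # -- convenience accessors ------------------------------------------------
    @property
    def te(self) -> EffectEstimate:
        return self._result.te

    @property
    def cde(self) -> EffectEstimate:
        return self._result.cde

    @property
    def pct_mediation(self) -> float:
        return self._result.pct_mediation

    @property
    def pct_mediation_ci(self):
        return self._result.pct_mediation_ci

    @property
    def bootstrap_se(self) -> dict[str, float]:
        return self._result.bootstrap_se

    @property
    def balance(self):
        """Balance reports per mode ('te', 'cde')."""
        return self._result._balance

    def to_frame(self) -> pd.DataFrame:
        """One row per quantity, Table-1 layout."""
        def fmt(est: EffectEstimate):
            return {
                "odds_ratio": est.odds_ratio,
                "or_lo": est.or_ci[0] if est.or_ci else np.nan,
                "or_hi": est.or_ci[1] if est.or_ci else np.nan,
                "risk_difference_pp": est.risk_difference_pp,
                "rd_lo": est.rd_ci[0] if est.rd_ci else np.nan,
                "rd_hi": est.rd_ci[1] if est.rd_ci else np.nan,
                "prevalence_unexposed_pp": est.prevalence_unexposed_pp,
                "paf_pct": est.paf_pct,
            }

        df = pd.DataFrame({"total_effect": fmt(self.te), "direct_effect": fmt(self.cde)})
        df.loc["pct_mediation", "total_effect"] = self.pct_mediation
        if self.pct_mediation_ci:
            df.loc["pct_mediation_lo", "total_effect"] = self.pct_mediation_ci[0]
            df.loc["pct_mediation_hi", "total_effect"] = self.pct_mediation_ci[1]
        return df

    def summary(self) -> str:
        def ci(x, pair, fmt="{:.2f}"):
            if pair is None:
                return fmt.format(x)
            return f"{fmt.format(x)} ({fmt.format(pair[0])}-{fmt.format(pair[1])})"

        te, cde = self.te, self.cde
        lines = [
            "Marginal structural mediation analysis (weighted pooled logistic outcome model)",
            f"mode: {self.config.mode}   persons: {te.n_individuals}   "
            f"observations: {te.n_observations}   bootstrap B: {self._result.n_boot}",
            "-" * 78,
            f"{'':28s}{'Total effect':>24s}{'Direct effect':>24s}",
            f"{'Odds ratio':28s}{ci(te.odds_ratio, te.or_ci):>24s}{ci(cde.odds_ratio, cde.or_ci):>24s}",
            f"{'Risk difference (pp)':28s}{ci(te.risk_difference_pp, te.rd_ci):>24s}"
            f"{ci(cde.risk_difference_pp, cde.rd_ci):>24s}",
            f"{'Prevalence unexposed (%)':28s}{ci(te.prevalence_unexposed_pp, te.prevalence_unexposed_ci):>24s}"
            f"{ci(cde.prevalence_unexposed_pp, cde.prevalence_unexposed_ci):>24s}",
            f"{'PAF (%)':28s}{te.paf_pct:>24.2f}{cde.paf_pct:>24.2f}",
            f"{'% mediation':28s}{ci(self.pct_mediation, self.pct_mediation_ci):>24s}",
            "-" * 78,
            f"max post-weighting SMD: TE {self.balance['te'].max_post:.3f}, "
            f"CDE {self.balance['cde'].max_post:.3f}",
        ]
        return "\n".join(lines)

    def plot_balance(self, mode: str = "te", ax=None):
        """Love plot of pre- vs post-weighting standardised mean differences."""
        import matplotlib.pyplot as plt

        report = self.balance[mode].table.sort_values("smd_pre")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * len(report) + 1.5))
        y = np.arange(len(report))
        ax.scatter(report["smd_pre"], y, label="unweighted", marker="o", facecolors="none",
                   edgecolors="tab:red")
        ax.scatter(report["smd_post"], y, label="weighted", marker="o", color="tab:blue")
        ax.axvline(0.1, color="grey", ls="--", lw=0.8)
        ax.axvline(0.2, color="grey", ls=":", lw=0.8)
        ax.set_yticks(y, report["covariate"])
        ax.set_xlabel("standardised mean difference")
        ax.legend(frameon=False)
        return ax

    def to_dict(self) -> dict:
        return self._result.to_dict()
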