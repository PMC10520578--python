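"""Synthetic longitudinal employment/income/mental-health panels.

Generates annual person-by-wave panels with the causal structure used
throughout the package: paid employment (exposure) affects equivalised
household income instantaneously within the same wave, and both employment
and income affect the probability of common-mental-disorder caseness
(GHQ-12 score >= 4).  Time-invariant confounders (gender, ethnicity,
education), time-varying confounders (housing tenure, benefits receipt,
relationship status, number of children, physical-health score, region)
and the feedback loops between past mental health, past income and current
employment are all represented so that inverse-probability-weighted
estimators face genuine time-varying confounding.

Because the data-generating process is fully known, interventional
("oracle") values of the total effect and controlled direct effect are
available by Monte-Carlo simulation from the structural equations
(:func:`oracle_effects`); estimator recovery can therefore be judged
against ground truth rather than against another estimator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "SimTruth",
    "generate_panel",
    "oracle_effects",
    "inject_missingness",
]

#: Reference point for log-income terms (roughly log of median monthly
#: equivalised income in pounds); centring only, no behavioural content.
LOG_INCOME_REF = 7.3


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimParams:
    """Structural parameters of the synthetic panel.

    All logistic coefficients are on the log-odds scale; income
    coefficients are on the natural-log scale of monthly equivalised
    household income after housing costs.  Defaults are calibrated so a
    large panel reproduces the headline descriptive features of a UK
    working-age cohort: ~25.7% of person-waves out of paid work, mean
    income loss on a move into non-employment near 295 pounds/month, and
    caseness prevalence in the high teens.
    """

    n_individuals: int = 1000
    n_waves: int = 9
    seed: int = 0

    # -- baseline composition ------------------------------------------------
    p_female: float = 0.553
    p_nonwhite: float = 0.14
    educ_probs: tuple[float, float, float] = (0.42, 0.37, 0.21)  # high/med/low
    age_min: int = 25
    age_max_baseline: int = 56  # +8 annual waves keeps everyone <= 64
    n_regions: int = 12

    # -- employment process (logit of being employed) ------------------------
    emp_intercept: float = -0.293
    emp_intercept_wave1: float = 2.460
    emp_persist: float = 3.30       # log-odds on employed at t-1
    emp_caseness_lag: float = -0.40
    emp_log_income_lag: float = 0.25
    emp_benefits_lag: float = -0.60
    emp_renter_lag: float = -0.30
    emp_educ_med: float = -0.25
    emp_educ_low: float = -0.65
    emp_female: float = -0.45
    emp_age: float = -0.012         # per year of age, centred at 45
    emp_pcs_lag: float = 0.035      # per point of PCS, centred at 50

    # -- income equation (log monthly equivalised income, after housing) -----
    inc_intercept: float = 7.2455
    inc_employed: float = 0.2292
    inc_educ_med: float = -0.16
    inc_educ_low: float = -0.32
    inc_female: float = -0.04
    inc_age: float = 0.004
    inc_ar: float = 0.60            # AR(1) persistence of the income residual
    inc_sd: float = 0.30            # innovation s.d. of the AR(1) residual
    housing_cost_fraction: float = 0.25  # share of gross income absorbed by housing

    # -- outcome equation (logit of GHQ-12 caseness) --------------------------
    out_intercept: float = -1.9825
    beta_A: float = 0.3804            # direct effect of non-employment
    beta_M: float = -0.2490           # per log-income unit (mediated path)
    beta_M_older_scale: float = 1.0  # multiplies beta_M when age >= 41
    out_caseness_lag: float = 1.25
    out_female: float = 0.28
    out_educ_med: float = 0.05
    out_educ_low: float = 0.12
    out_pcs_lag: float = -0.035
    out_age: float = -0.004

    # -- time-varying confounder dynamics -------------------------------------
    p_renter_by_educ: tuple[float, float, float] = (0.22, 0.32, 0.48)
    renter_persist: float = 0.96
    p_benefits_if_employed: float = 0.12
    p_benefits_if_not: float = 0.55
    p_couple: float = 0.72
    couple_persist: float = 0.96
    children_mean: float = 0.9
    p_child_gain: float = 0.05
    p_child_leave: float = 0.07
    pcs_ar: float = 0.70
    pcs_sd: float = 5.0
    pcs_age_slope: float = -0.15
    mcs_caseness_shift: float = -9.0
    mcs_sd: float = 7.0

    # -- missingness (used by inject_missingness only) ------------------------
    wave_nonresponse: float = 0.06
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "income": 0.04,
            "ghq": 0.03,
            "pcs": 0.03,
            "mcs": 0.03,
            "tenure": 0.01,
            "benefits": 0.01,
            "couple": 0.01,
            "employed": 0.01,
        }
    )
    #: log-odds shift of missingness for women (MAR driver; gender is
    #: always observed).
    missing_female_shift: float = 0.35
    missing_age_slope: float = 0.01

    def validate(self) -> None:
        probs = {
            "p_female": self.p_female,
            "p_nonwhite": self.p_nonwhite,
            "wave_nonresponse": self.wave_nonresponse,
            "p_benefits_if_employed": self.p_benefits_if_employed,
            "p_benefits_if_not": self.p_benefits_if_not,
            "p_couple": self.p_couple,
            "couple_persist": self.couple_persist,
            "renter_persist": self.renter_persist,
            "p_child_gain": self.p_child_gain,
            "p_child_leave": self.p_child_leave,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} is not a probability")
        for name, p in dict(self.missing_rates).items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"missing_rates[{name!r}]={p} is not a probability")
        if abs(sum(self.educ_probs) - 1.0) > 1e-9 or min(self.educ_probs) < 0:
            raise ConfigurationError("educ_probs must be non-negative and sum to 1")
        if len(self.p_renter_by_educ) != 3:
            raise ConfigurationError("p_renter_by_educ needs one probability per education level")
        for p in self.p_renter_by_educ:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("p_renter_by_educ entries must be probabilities")
        if self.n_waves < 2:
            raise ConfigurationError("n_waves must be >= 2 (lagged covariates are required)")
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be positive")
        if self.inc_sd <= 0 or self.pcs_sd <= 0 or self.mcs_sd <= 0:
            raise ConfigurationError("noise standard deviations must be positive")
        if not 0.0 <= self.housing_cost_fraction < 1.0:
            raise ConfigurationError("housing_cost_fraction must lie in [0, 1)")

    def replace(self, **changes) -> "SimParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["missing_rates"] = dict(d["missing_rates"])
        return d


@dataclass
class SimTruth:
    """Oracle interventional effects implied by a :class:`SimParams`.

    Risk differences are in percentage points; ``pct_mediation`` follows
    the attenuation definition 100 x (TE - CDE) / TE.
    """

    params: SimParams
    oracle_TE_rd: float
    oracle_CDE_rd: float
    oracle_pct_mediation: float
    monte_carlo_se: float
    n_mc: int

    def to_dict(self) -> dict:
        return {
            "oracle_TE_rd": self.oracle_TE_rd,
            "oracle_CDE_rd": self.oracle_CDE_rd,
            "oracle_pct_mediation": self.oracle_pct_mediation,
            "monte_carlo_se": self.monte_carlo_se,
            "n_mc": self.n_mc,
            "params": self.params.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# structural equations (shared by generate_panel and oracle_effects)
# ---------------------------------------------------------------------------


class _Structural:
    """Vectorised structural equations for a cohort of n individuals."""

    def __init__(self, params: SimParams, n: int, rng: np.random.Generator):
        self.p = params
        self.n = n
        self.rng = rng

    def draw_baseline(self) -> dict[str, np.ndarray]:
        p, n, rng = self.p, self.n, self.rng
        female = (rng.random(n) < p.p_female).astype(np.int8)
        nonwhite = (rng.random(n) < p.p_nonwhite).astype(np.int8)
        educ = rng.choice(3, size=n, p=list(p.educ_probs))  # 0 high, 1 med, 2 low
        age0 = rng.integers(p.age_min, p.age_max_baseline + 1, size=n)
        region = rng.integers(0, p.n_regions, size=n)
        return dict(female=female, nonwhite=nonwhite, educ=educ, age0=age0, region=region)

    # --- linear predictors ---------------------------------------------------

    def emp_lp_wave1(self, b, age):
        p = self.p
        return (
            p.emp_intercept_wave1
            + p.emp_educ_med * (b["educ"] == 1)
            + p.emp_educ_low * (b["educ"] == 2)
            + p.emp_female * b["female"]
            + p.emp_age * (age - 45.0)
        )

    def emp_lp(self, b, age, emp_l, case_l, loginc_l, ben_l, renter_l, pcs_l):
        p = self.p
        return (
            p.emp_intercept
            + p.emp_persist * emp_l
            + p.emp_caseness_lag * case_l
            + p.emp_log_income_lag * (loginc_l - LOG_INCOME_REF)
            + p.emp_benefits_lag * ben_l
            + p.emp_renter_lag * renter_l
            + p.emp_educ_med * (b["educ"] == 1)
            + p.emp_educ_low * (b["educ"] == 2)
            + p.emp_female * b["female"]
            + p.emp_age * (age - 45.0)
            + p.emp_pcs_lag * (pcs_l - 50.0)
        )

    def income_base(self, b, age, emp):
        """Systematic part of log income given employment status."""
        p = self.p
        return (
            p.inc_intercept
            + p.inc_employed * emp
            + p.inc_educ_med * (b["educ"] == 1)
            + p.inc_educ_low * (b["educ"] == 2)
            + p.inc_female * b["female"]
            + p.inc_age * (age - 45.0)
        )

    def outcome_lp(self, b, age, unemp, loginc, case_l, pcs_l):
        p = self.p
        beta_m = p.beta_M * np.where(age >= 41, p.beta_M_older_scale, 1.0)
        return (
            p.out_intercept
            + p.beta_A * unemp
            + beta_m * (loginc - LOG_INCOME_REF)
            + p.out_caseness_lag * case_l
            + p.out_female * b["female"]
            + p.out_educ_med * (b["educ"] == 1)
            + p.out_educ_low * (b["educ"] == 2)
            + p.out_pcs_lag * (pcs_l - 50.0)
            + p.out_age * (age - 45.0)
        )

    def outcome_lp_wave1(self, b, age, unemp, loginc):
        # no lags available at the first wave; PCS enters concurrently and
        # the lagged-caseness term is replaced by its prevalence-weighted
        # average via the intercept (adds 0.25 to keep wave-1 prevalence
        # close to later waves)
        p = self.p
        beta_m = p.beta_M * np.where(age >= 41, p.beta_M_older_scale, 1.0)
        return (
            p.out_intercept
            + 0.25
            + p.beta_A * unemp
            + beta_m * (loginc - LOG_INCOME_REF)
            + p.out_female * b["female"]
            + p.out_educ_med * (b["educ"] == 1)
            + p.out_educ_low * (b["educ"] == 2)
            + p.out_age * (age - 45.0)
        )


def _ghq_from_caseness(case: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integer GHQ-12 score consistent with the caseness indicator."""
    n = case.shape[0]
    high = 4 + rng.binomial(8, 0.35, size=n)
    low = rng.binomial(3, 0.40, size=n)
    return np.where(case == 1, high, low).astype(np.int16)


def generate_panel(params: SimParams) -> pd.DataFrame:
    """Simulate a complete long-format person-by-wave panel.

    Returns one row per person-wave with employment, income (monthly
    equivalised, after housing costs), GHQ-12 score and every confounder.
    Household composition columns (``n_adults``, ``household_income``)
    are included so that income equivalisation can be exercised; the
    analysis income column is already on the equivalised scale.
    Deterministic given ``params.seed``.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 20221201]))
    n, T = p.n_individuals, p.n_waves
    s = _Structural(p, n, rng)
    b = s.draw_baseline()

    z_stat_sd = p.inc_sd / np.sqrt(1.0 - p.inc_ar**2)
    educ_idx = b["educ"]
    renter = (rng.random(n) < np.asarray(p.p_renter_by_educ)[educ_idx]).astype(np.int8)
    couple = (rng.random(n) < p.p_couple).astype(np.int8)
    children = rng.poisson(p.children_mean, size=n).clip(max=5).astype(np.int16)

    rows = []
    emp_l = case_l = loginc_l = ben_l = renter_l = pcs_l = None
    pcs_resid = rng.normal(0.0, p.pcs_sd / np.sqrt(1 - p.pcs_ar**2), size=n)
    z = rng.normal(0.0, z_stat_sd, size=n)

    for t in range(1, T + 1):
        age = b["age0"] + (t - 1)
        if t == 1:
            emp = (rng.random(n) < _expit(s.emp_lp_wave1(b, age))).astype(np.int8)
        else:
            lp = s.emp_lp(b, age, emp_l, case_l, loginc_l, ben_l, renter_l, pcs_l)
            emp = (rng.random(n) < _expit(lp)).astype(np.int8)

        if t > 1:
            z = p.inc_ar * z + rng.normal(0.0, p.inc_sd, size=n)
            # confounder transitions
            stay = rng.random(n) < p.renter_persist
            renter = np.where(stay, renter, 1 - renter).astype(np.int8)
            stay = rng.random(n) < p.couple_persist
            couple = np.where(stay, couple, 1 - couple).astype(np.int8)
            gain = rng.random(n) < p.p_child_gain
            leave = (rng.random(n) < p.p_child_leave) & (children > 0)
            children = (children + gain.astype(np.int16) - leave.astype(np.int16)).clip(0, 5)
            pcs_resid = p.pcs_ar * pcs_resid + rng.normal(0.0, p.pcs_sd, size=n)

        loginc = s.income_base(b, age, emp) + z
        income = np.exp(loginc)
        pcs = 50.0 + p.pcs_age_slope * (age - 45.0) + pcs_resid

        p_ben = np.where(emp == 1, p.p_benefits_if_employed, p.p_benefits_if_not)
        benefits = (rng.random(n) < p_ben).astype(np.int8)

        unemp = 1 - emp
        if t == 1:
            lp_y = s.outcome_lp_wave1(b, age, unemp, loginc)
        else:
            lp_y = s.outcome_lp(b, age, unemp, loginc, case_l, pcs_l)
        case = (rng.random(n) < _expit(lp_y)).astype(np.int8)
        ghq = _ghq_from_caseness(case, rng)
        mcs = 52.0 + p.mcs_caseness_shift * case + rng.normal(0.0, p.mcs_sd, size=n)

        n_adults = 1 + couple.astype(np.int16)
        oecd = 1.0 + 0.5 * (n_adults - 1) + 0.3 * children
        rows.append(
            pd.DataFrame(
                {
                    "pid": np.arange(n),
                    "wave": t,
                    "age": age,
                    "female": b["female"],
                    "nonwhite": b["nonwhite"],
                    "educ": pd.Categorical.from_codes(
                        educ_idx, categories=["high", "med", "low"]
                    ),
                    "region": pd.Categorical.from_codes(
                        b["region"], categories=[f"r{i+1:02d}" for i in range(p.n_regions)]
                    ),
                    "tenure": renter.copy(),
                    "benefits": benefits,
                    "couple": couple.copy(),
                    "n_children": children.copy(),
                    "n_adults": n_adults,
                    "pcs": pcs,
                    "mcs": mcs,
                    "employed": emp,
                    "income": income,
                    "household_income": income * oecd,
                    "ghq": ghq,
                }
            )
        )

        emp_l, case_l, loginc_l = emp, case, loginc
        ben_l, renter_l, pcs_l = benefits, renter, pcs

    panel = pd.concat(rows, ignore_index=True)
    panel = panel.sort_values(["pid", "wave"], kind="mergesort").reset_index(drop=True)
    return panel


def oracle_effects(params: SimParams, n_mc: int = 200_000, seed: int | None = None) -> SimTruth:
    """Brute-force interventional total and controlled direct effects.

    Simulates the natural history of ``n_mc`` individuals from the
    structural equations and, at every wave after the first, evaluates the
    caseness risk under ``do(A = not employed)`` versus ``do(A = employed)``
    holding the person's natural history fixed.  Income responds to the
    intervened exposure through its own equation (same residual draw in
    both arms).  The controlled direct effect uses the employed-arm income
    in both arms, so only the direct pathway remains.  Risks are averaged
    analytically over the Bernoulli outcome (the logistic probability is
    used directly), which keeps the Monte-Carlo error small.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(
        np.random.SeedSequence([p.seed if seed is None else seed, 77003])
    )
    n, T = n_mc, p.n_waves
    s = _Structural(p, n, rng)
    b = s.draw_baseline()
    z_stat_sd = p.inc_sd / np.sqrt(1.0 - p.inc_ar**2)

    educ_idx = b["educ"]
    renter = (rng.random(n) < np.asarray(p.p_renter_by_educ)[educ_idx]).astype(np.int8)
    couple = (rng.random(n) < p.p_couple).astype(np.int8)
    children = rng.poisson(p.children_mean, size=n).clip(max=5).astype(np.int16)
    pcs_resid = rng.normal(0.0, p.pcs_sd / np.sqrt(1 - p.pcs_ar**2), size=n)
    z = rng.normal(0.0, z_stat_sd, size=n)

    te_contrasts = []
    cde_contrasts = []
    emp_l = case_l = loginc_l = ben_l = renter_l = pcs_l = None

    for t in range(1, T + 1):
        age = b["age0"] + (t - 1)
        if t == 1:
            emp = (rng.random(n) < _expit(s.emp_lp_wave1(b, age))).astype(np.int8)
        else:
            lp = s.emp_lp(b, age, emp_l, case_l, loginc_l, ben_l, renter_l, pcs_l)
            emp = (rng.random(n) < _expit(lp)).astype(np.int8)
            z = p.inc_ar * z + rng.normal(0.0, p.inc_sd, size=n)
            stay = rng.random(n) < p.renter_persist
            renter = np.where(stay, renter, 1 - renter).astype(np.int8)
            stay = rng.random(n) < p.couple_persist
            couple = np.where(stay, couple, 1 - couple).astype(np.int8)
            gain = rng.random(n) < p.p_child_gain
            leave = (rng.random(n) < p.p_child_leave) & (children > 0)
            children = (children + gain.astype(np.int16) - leave.astype(np.int16)).clip(0, 5)
            pcs_resid = p.pcs_ar * pcs_resid + rng.normal(0.0, p.pcs_sd, size=n)

        loginc = s.income_base(b, age, emp) + z
        pcs = 50.0 + p.pcs_age_slope * (age - 45.0) + pcs_resid
        p_ben = np.where(emp == 1, p.p_benefits_if_employed, p.p_benefits_if_not)
        benefits = (rng.random(n) < p_ben).astype(np.int8)

        if t > 1:
            # interventional incomes share the natural residual z
            loginc_emp = s.income_base(b, age, np.ones(n)) + z
            loginc_unemp = s.income_base(b, age, np.zeros(n)) + z
            p_unemp = _expit(s.outcome_lp(b, age, 1.0, loginc_unemp, case_l, pcs_l))
            p_emp = _expit(s.outcome_lp(b, age, 0.0, loginc_emp, case_l, pcs_l))
            p_unemp_cde = _expit(s.outcome_lp(b, age, 1.0, loginc_emp, case_l, pcs_l))
            te_contrasts.append(p_unemp - p_emp)
            cde_contrasts.append(p_unemp_cde - p_emp)

        unemp = 1 - emp
        if t == 1:
            lp_y = s.outcome_lp_wave1(b, age, unemp, loginc)
        else:
            lp_y = s.outcome_lp(b, age, unemp, loginc, case_l, pcs_l)
        case = (rng.random(n) < _expit(lp_y)).astype(np.int8)

        emp_l, case_l, loginc_l = emp, case, loginc
        ben_l, renter_l, pcs_l = benefits, renter, pcs

    te = np.concatenate(te_contrasts)
    cde = np.concatenate(cde_contrasts)
    te_rd = 100.0 * float(te.mean())
    cde_rd = 100.0 * float(cde.mean())
    # conservative s.e.: contrasts within a person correlate across waves,
    # so use the person as the sampling unit
    per_person_te = np.mean(np.stack(te_contrasts), axis=0)
    mc_se = 100.0 * float(per_person_te.std(ddof=1) / np.sqrt(n))
    pct = float("nan") if te_rd == 0 else 100.0 * (te_rd - cde_rd) / te_rd
    return SimTruth(
        params=params,
        oracle_TE_rd=te_rd,
        oracle_CDE_rd=cde_rd,
        oracle_pct_mediation=pct,
        monte_carlo_se=mc_se,
        n_mc=n_mc,
    )


#: Variables eligible for item-level missingness injection.
_MISSABLE = ["employed", "income", "ghq", "pcs", "mcs", "tenure", "benefits", "couple", "n_children"]


def inject_missingness(panel: pd.DataFrame, params: SimParams) -> pd.DataFrame:
    """Blank values under a missing-at-random mechanism.

    Two layers: whole-interview nonresponse (all substantive variables of
    a person-wave blanked at once) and independent item nonresponse at the
    per-variable rates in ``params.missing_rates``.  Both probabilities
    depend only on always-observed covariates (gender, age, wave), so the
    mechanism is MAR by construction.  Wave-1 rows are exempt from
    whole-interview nonresponse so every person retains a baseline record.
    """
    params.validate()
    p = params
    rates = {k: float(v) for k, v in dict(p.missing_rates).items() if v > 0}
    if p.wave_nonresponse <= 0 and not rates:
        return panel.copy()
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 550291]))
    out = panel.copy()
    n = len(out)
    female = out["female"].to_numpy(dtype=float)
    age = out["age"].to_numpy(dtype=float)

    def _mar_prob(base_rate: float) -> np.ndarray:
        if base_rate <= 0.0:
            return np.zeros(n)
        if base_rate >= 1.0:
            return np.ones(n)
        base = np.log(base_rate / (1 - base_rate))
        lp = base + p.missing_female_shift * (female - p.p_female) + p.missing_age_slope * (age - 45.0)
        prob = _expit(lp)
        # recentre so the marginal rate matches the target
        prob *= base_rate / prob.mean()
        return prob.clip(0.0, 1.0)

    affected = set(_MISSABLE) if p.wave_nonresponse > 0 else set(rates)
    for col in affected:
        if col in out.columns and out[col].dtype.kind in "iub":
            out[col] = out[col].astype(float)

    wave_miss = (rng.random(n) < _mar_prob(p.wave_nonresponse)) & (out["wave"].to_numpy() > 1)
    if p.wave_nonresponse > 0:
        for col in _MISSABLE:
            if col in out.columns:
                out.loc[wave_miss, col] = np.nan

    for col, rate in rates.items():
        if col not in out.columns:
            continue
        item = rng.random(n) < _mar_prob(rate)
        out.loc[item, col] = np.nan
    return out
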