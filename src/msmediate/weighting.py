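"""Stabilised inverse-probability weights and covariate balance diagnostics.

For the total effect, each person-wave receives a stabilised exposure
weight

    sw_A = P(A = a_obs) / P(A = a_obs | V, L_lag)

with the denominator conditioning on the full adjustment set (baseline
confounders plus every one-wave-lagged time-varying confounder, lagged
exposure, lagged caseness, lagged MCS and lagged income) and, by default,
the marginal exposure probability as the numerator, so the weighted
pseudo-population breaks every exposure-confounder association (a
conditional numerator is available; see ``_exposure_terms``).  For the
controlled direct effect an additional mediator weight blocks the income
pathway:

    sw_M = f(M | A, V) / f(M | A, V, L_lag)

where both conditional densities of log income are Gaussian linear
regressions with fitted residual standard deviation.  Binary poverty is a
deterministic function of income given the poverty line, so it receives no
separate weight and enters the outcome model as a covariate instead.

Balance is assessed by standardised mean differences between exposure
groups before and after weighting, with 0.1 (negligible difference) and
0.2 (reasonable balance) as the conventional thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import build_design
from .outcome import weighted_logistic, predict_proba
from .preprocess import VariableRoles

__all__ = [
    "WeightSet",
    "BalanceReport",
    "fit_exposure_weights",
    "fit_mediator_weights",
    "truncate_weights",
    "smd",
    "balance_report",
]

SMD_NEGLIGIBLE = 0.1
SMD_REASONABLE = 0.2


@dataclass
class WeightSet:
    """Per-observation stabilised weights with truncation diagnostics."""

    sw_A: np.ndarray
    sw_M: np.ndarray | None = None
    truncation: tuple[float, float] | None = None
    fraction_truncated: float = 0.0

    @property
    def w(self) -> np.ndarray:
        """Combined weight (exposure x mediator)."""
        return self.sw_A if self.sw_M is None else self.sw_A * self.sw_M

    def summary(self) -> dict:
        w = self.w
        return {
            "mean": float(w.mean()),
            "sd": float(w.std(ddof=1)),
            "min": float(w.min()),
            "max": float(w.max()),
            "fraction_truncated": float(self.fraction_truncated),
            "mode": "CDE" if self.sw_M is not None else "TE",
        }


def _exposure_terms(
    roles: VariableRoles, numerator: str = "marginal"
) -> tuple[list[str], list[str]]:
    """Numerator/denominator covariate lists for the exposure weight.

    The default numerator is the marginal exposure probability (classic
    stabilised weight): the weighted pseudo-population then breaks the
    association between the exposure and *every* confounder, which is what
    an SMD balance check after weighting assesses.  A ``"conditional"``
    numerator (baseline confounders + lagged exposure) gives less variable
    weights at the price of leaving its conditioning covariates imbalanced
    by construction; those covariates are then handled by the outcome
    model only.
    """
    den = list(roles.adjustment_set)
    if numerator == "marginal":
        num: list[str] = []
    elif numerator == "conditional":
        num = list(roles.baseline)
        if "unemployed_lag" in roles.extra_lags:
            num.append("unemployed_lag")
    else:
        raise ValueError(f"unknown numerator form {numerator!r}")
    return num, den


def fit_exposure_weights(
    table: pd.DataFrame,
    roles: VariableRoles | None = None,
    *,
    numerator: str = "marginal",
    start_num: np.ndarray | None = None,
    start_den: np.ndarray | None = None,
    max_iter: int = 100,
) -> WeightSet:
    """Stabilised inverse-probability-of-exposure weights (TE mode)."""
    roles = roles or VariableRoles()
    a = table[roles.exposure].to_numpy(dtype=np.float64)
    num_terms, den_terms = _exposure_terms(roles, numerator)
    dm_num = build_design(table, num_terms)
    dm_den = build_design(table, den_terms)
    fit_num = weighted_logistic(dm_num.X, a, names=dm_num.names, start=start_num, max_iter=max_iter, check_rank=False)
    fit_den = weighted_logistic(dm_den.X, a, names=dm_den.names, start=start_den, max_iter=max_iter, check_rank=False)
    p_num = predict_proba(fit_num, dm_num.X)
    p_den = predict_proba(fit_den, dm_den.X)
    sw = np.where(a == 1, p_num / p_den, (1 - p_num) / (1 - p_den))
    ws = WeightSet(sw_A=sw)
    ws.fits = {"numerator": fit_num, "denominator": fit_den}  # type: ignore[attr-defined]
    return ws


def _gaussian_density_ratio(
    m: np.ndarray, X_num: np.ndarray, X_den: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Ratio of two fitted Gaussian conditional densities of the mediator."""
    out = {}
    dens = []
    for key, X in (("numerator", X_num), ("denominator", X_den)):
        beta, *_ = np.linalg.lstsq(X, m, rcond=None)
        resid = m - X @ beta
        dof = max(len(m) - X.shape[1], 1)
        sigma = float(np.sqrt(resid @ resid / dof))
        if sigma < 1e-8:
            raise ValueError("degenerate mediator density: residual s.d. ~ 0")
        dens.append(np.exp(-0.5 * (resid / sigma) ** 2) / sigma)
        out[key] = {"beta": beta, "sigma": sigma}
    ratio = dens[0] / dens[1]
    return ratio, out


def fit_mediator_weights(
    table: pd.DataFrame,
    roles: VariableRoles | None = None,
    *,
    exposure_weights: WeightSet | None = None,
) -> WeightSet:
    """Add stabilised mediator (log-income) weights for CDE estimation.

    If ``exposure_weights`` is given its sw_A is reused; otherwise
    exposure weights are fitted first.  Returns a WeightSet whose combined
    weight is sw_A x sw_M.
    """
    roles = roles or VariableRoles()
    ws = exposure_weights or fit_exposure_weights(table, roles)
    m = table[roles.mediator_continuous].to_numpy(dtype=np.float64)
    num_terms = [roles.exposure] + list(roles.baseline) + list(roles.age_terms)
    den_terms = [roles.exposure] + list(roles.adjustment_set)
    X_num = build_design(table, num_terms).X
    X_den = build_design(table, den_terms).X
    ratio, fits = _gaussian_density_ratio(m, X_num, X_den)
    return WeightSet(sw_A=ws.sw_A, sw_M=ratio)


def truncate_weights(ws: WeightSet, lower_pct: float = 1.0, upper_pct: float = 99.0) -> WeightSet:
    """Clip combined weights to empirical percentiles of their distribution.

    The clip is applied to the exposure weight (TE mode) or to the
    mediator component (CDE mode, so the product respects the bound
    structure); the fraction of observations touched is recorded.
    """
    if not (0 < lower_pct < 50 < upper_pct < 100):
        raise ValueError("percentiles must satisfy 0 < lower < 50 < upper < 100")
    w = ws.w
    lo, hi = np.percentile(w, [lower_pct, upper_pct])
    clipped = np.clip(w, lo, hi)
    frac = float(np.mean((w < lo) | (w > hi)))
    if ws.sw_M is None:
        return WeightSet(sw_A=clipped, truncation=(float(lo), float(hi)), fraction_truncated=frac)
    # preserve the product after clipping
    return WeightSet(
        sw_A=ws.sw_A,
        sw_M=clipped / ws.sw_A,
        truncation=(float(lo), float(hi)),
        fraction_truncated=frac,
    )


def _weighted_mean_var(x: np.ndarray, w: np.ndarray, binary: bool) -> tuple[float, float]:
    mean = float(np.sum(w * x) / np.sum(w))
    if binary:
        return mean, mean * (1.0 - mean)
    var = float(np.sum(w * (x - mean) ** 2) / np.sum(w))
    return mean, var


def smd(
    values: np.ndarray,
    group: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Standardised mean difference between the two exposure groups.

    |x1 - x0| / sqrt((s1^2 + s0^2) / 2) with weighted means and variances;
    binary covariates use proportions and p(1-p) variances.  Returns +inf
    when the pooled variance is zero but the means differ.
    """
    values = np.asarray(values, dtype=np.float64)
    group = np.asarray(group)
    w = np.ones(len(values)) if weights is None else np.asarray(weights, dtype=np.float64)
    m1, m0 = group == 1, group == 0
    if m1.sum() == 0 or m0.sum() == 0:
        raise ValueError("both exposure groups must be non-empty")
    uniq = np.unique(values[~np.isnan(values)])
    binary = uniq.size <= 2 and np.all(np.isin(uniq, [0.0, 1.0]))
    mean1, var1 = _weighted_mean_var(values[m1], w[m1], binary)
    mean0, var0 = _weighted_mean_var(values[m0], w[m0], binary)
    pooled = (var1 + var0) / 2.0
    diff = abs(mean1 - mean0)
    if pooled <= 0:
        return 0.0 if diff == 0 else float("inf")
    return diff / float(np.sqrt(pooled))


@dataclass
class BalanceReport:
    """Pre- and post-weighting SMD per covariate with threshold flags."""

    table: pd.DataFrame
    thresholds: tuple[float, float] = (SMD_NEGLIGIBLE, SMD_REASONABLE)

    @property
    def max_post(self) -> float:
        return float(self.table["smd_post"].max())

    def all_balanced(self, threshold: float | None = None) -> bool:
        return self.table["smd_post"].max() < (threshold or self.thresholds[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def balance_report(
    table: pd.DataFrame,
    roles: VariableRoles | None = None,
    ws: WeightSet | None = None,
) -> BalanceReport:
    """SMD of every adjustment-set covariate, unweighted and weighted.

    Categorical covariates expand to one indicator per level; the output
    is tidy (one row per covariate/level) and directly plottable as a
    love plot.
    """
    roles = roles or VariableRoles()
    if ws is None:
        raise ValueError("weights are required; fit them first")
    a = table[roles.exposure].to_numpy(dtype=np.float64)
    w = ws.w
    rows = []
    for cov in roles.adjustment_set:
        dm = build_design(table[[cov]], [cov], intercept=False, drop_constant=False)
        for j, name in enumerate(dm.names):
            x = dm.X[:, j]
            pre = smd(x, a)
            post = smd(x, a, w)
            rows.append(
                {
                    "covariate": name,
                    "smd_pre": pre,
                    "smd_post": post,
                    "negligible_post": post < SMD_NEGLIGIBLE,
                    "reasonable_post": post < SMD_REASONABLE,
                }
            )
    return BalanceReport(pd.DataFrame(rows))
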