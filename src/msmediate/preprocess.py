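"""Analysis-variable derivation and lagged-table construction.

The raw panel carries one row per person-wave with employment, monthly
equivalised household income (after housing costs), the GHQ-12 score and
confounders.  This module derives the analysis variables — caseness
(GHQ-12 >= 4), relative poverty (income below 60% of the sample median),
log income with a positive floor — and builds the lagged analysis table in
which each wave-t outcome row carries the wave-(t-1) values of every
time-varying confounder, lagged exposure, lagged income and lagged mental
health, implementing the minimally sufficient adjustment set for the
short-term employment effect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CASENESS_CUTOFF",
    "POVERTY_FRACTION",
    "LOG_INCOME_FLOOR",
    "VariableRoles",
    "derive_caseness",
    "derive_poverty",
    "equivalise_income",
    "oecd_scale",
    "log_income",
    "restrict_sample",
    "build_analysis_table",
]

#: GHQ-12 score at or above which a person screens positive for common
#: mental disorder ("caseness").
CASENESS_CUTOFF = 4
#: Relative poverty line as a fraction of median equivalised income.
POVERTY_FRACTION = 0.6
#: Monthly income floor (currency units) applied before taking logs.
LOG_INCOME_FLOOR = 1.0
#: Working-age restriction.
AGE_MIN, AGE_MAX = 25, 64

LAG_SUFFIX = "_lag"


@dataclass(frozen=True)
class VariableRoles:
    """Column names per causal role in the analysis table.

    ``time_varying`` columns enter the models as one-wave lags; the four
    ``extra_lags`` (exposure, caseness, MCS, log income at t-1) complete
    the adjustment set.  ``drop_rule_variables`` is the list over which the
    high-missingness drop rule counts missing cells (22 names by default).
    """

    exposure: str = "unemployed"
    outcome: str = "caseness"
    mediator_continuous: str = "log_income"
    mediator_binary: str = "poverty"
    baseline: tuple[str, ...] = ("female", "nonwhite", "educ")
    age_terms: tuple[str, ...] = ("age", "age_sq")
    time_varying: tuple[str, ...] = ("tenure", "benefits", "couple", "n_children", "pcs")
    region: str | None = "region"
    extra_lags: tuple[str, ...] = (
        "unemployed_lag",
        "caseness_lag",
        "mcs_lag",
        "log_income_lag",
    )
    id_col: str = "pid"
    wave_col: str = "wave"
    drop_rule_variables: tuple[str, ...] = (
        # concurrent (13)
        "employed", "income", "ghq", "pcs", "tenure", "benefits", "couple",
        "n_children", "age", "female", "nonwhite", "educ", "region",
        # lagged (9)
        "employed_lag", "income_lag", "caseness_lag", "mcs_lag", "tenure_lag",
        "benefits_lag", "couple_lag", "n_children_lag", "pcs_lag",
    )

    @property
    def lagged_time_varying(self) -> tuple[str, ...]:
        return tuple(c + LAG_SUFFIX for c in self.time_varying)

    @property
    def adjustment_set(self) -> tuple[str, ...]:
        """Covariates of the weight-denominator and outcome models."""
        cols = self.baseline + self.age_terms + self.lagged_time_varying + self.extra_lags
        if self.region:
            cols = cols + (self.region,)
        return cols

    def replace(self, **changes) -> "VariableRoles":
        return dataclasses.replace(self, **changes)

    def validate_against(self, table: pd.DataFrame) -> None:
        roles = {
            "exposure": [self.exposure],
            "outcome": [self.outcome],
            "mediator": [self.mediator_continuous, self.mediator_binary],
            "baseline": list(self.baseline),
            "lagged": list(self.lagged_time_varying) + list(self.extra_lags),
        }
        seen: dict[str, str] = {}
        for role, names in roles.items():
            for name in names:
                if name in seen:
                    raise ValueError(f"column {name!r} assigned to both {seen[name]} and {role}")
                seen[name] = role
                if name not in table.columns:
                    raise KeyError(f"{role} column {name!r} not present in table")


def derive_caseness(ghq, cutoff: int = CASENESS_CUTOFF):
    """Binary common-mental-disorder indicator from a GHQ-12 score.

    Accepts scalars or array-likes; missing scores propagate as missing.
    Scores outside [0, 12] raise.
    """
    arr = pd.Series(np.asarray(ghq, dtype=float).ravel())
    valid = arr.dropna()
    if ((valid < 0) | (valid > 12)).any():
        bad = valid[(valid < 0) | (valid > 12)].iloc[0]
        raise ValueError(f"GHQ-12 score {bad} outside the 0-12 range")
    out = (arr >= cutoff).astype(float)
    out[arr.isna()] = np.nan
    if np.isscalar(ghq) or np.asarray(ghq).ndim == 0:
        v = out.iloc[0]
        return float(v) if not np.isnan(v) else np.nan
    return out.to_numpy()


def derive_poverty(
    panel: pd.DataFrame,
    income_col: str = "income",
    fraction: float = POVERTY_FRACTION,
) -> pd.DataFrame:
    """Flag rows below ``fraction`` of the sample median equivalised income.

    The median is computed once over every observed person-wave in the
    input table (an internal, unweighted poverty line); missing income
    yields missing poverty.
    """
    inc = panel[income_col]
    if inc.notna().sum() == 0:
        raise ValueError("cannot derive poverty: all incomes are missing")
    line = fraction * float(inc.median())
    out = panel.copy()
    pov = (inc < line).astype(float)
    pov[inc.isna()] = np.nan
    out["poverty"] = pov
    out.attrs["poverty_line"] = line
    out.attrs["poverty_median_source"] = "sample"
    return out


def oecd_scale(n_adults, n_children):
    """Modified-OECD equivalence scale: 1 + 0.5(adults-1) + 0.3*children."""
    n_adults = np.asarray(n_adults)
    if (n_adults < 1).any():
        raise ValueError("n_adults must be >= 1")
    return 1.0 + 0.5 * (n_adults - 1) + 0.3 * np.asarray(n_children)


def equivalise_income(household_income, n_adults, n_children):
    """Household income divided by the modified-OECD scale."""
    return np.asarray(household_income) / oecd_scale(n_adults, n_children)


def log_income(income, floor: float = LOG_INCOME_FLOOR):
    """Natural log of income floored at a small positive constant.

    Zero or negative equivalised incomes occur in survey data; flooring
    keeps the mediator finite without discarding the rows.  Missing
    propagates.
    """
    arr = np.asarray(income, dtype=float)
    out = np.log(np.maximum(arr, floor))
    out = np.where(np.isnan(arr), np.nan, out)
    if np.isscalar(income) or arr.ndim == 0:
        return float(out) if not np.isnan(out) else np.nan
    return out


def restrict_sample(panel: pd.DataFrame, age_min: int = AGE_MIN, age_max: int = AGE_MAX) -> pd.DataFrame:
    """Keep working-age rows (age within [age_min, age_max], inclusive)."""
    keep = (panel["age"] >= age_min) & (panel["age"] <= age_max)
    return panel.loc[keep].reset_index(drop=True)


def derive_analysis_variables(panel: pd.DataFrame) -> pd.DataFrame:
    """Add unemployed, caseness, poverty and log_income columns."""
    out = derive_poverty(panel)
    emp = out["employed"]
    unemp = (1.0 - emp).astype(float)
    unemp[emp.isna()] = np.nan
    out["unemployed"] = unemp
    out["caseness"] = derive_caseness(out["ghq"])
    out["log_income"] = log_income(out["income"].to_numpy())
    return out


def build_analysis_table(panel: pd.DataFrame, roles: VariableRoles | None = None) -> pd.DataFrame:
    """Pair each wave-t row with its wave-(t-1) covariate values.

    Rows whose previous wave is absent (a person's first observed wave, or
    a gap in participation) contribute no outcome row, mirroring the rule
    that the first wave only informs baseline confounding.  Adds ``age_sq``
    and lagged columns with the ``_lag`` suffix.  Raises on duplicate
    (person, wave) pairs.
    """
    roles = roles or VariableRoles()
    idc, wc = roles.id_col, roles.wave_col
    if panel.duplicated([idc, wc]).any():
        dup = panel[panel.duplicated([idc, wc], keep=False)].iloc[0]
        raise ValueError(f"duplicate (person, wave) pair: ({dup[idc]}, {dup[wc]})")
    df = panel.sort_values([idc, wc], kind="mergesort").reset_index(drop=True)

    lag_sources = {
        "employed": "employed_lag",
        "income": "income_lag",
        "log_income": "log_income_lag",
        "unemployed": "unemployed_lag",
        "caseness": "caseness_lag",
        "mcs": "mcs_lag",
        **{c: c + LAG_SUFFIX for c in roles.time_varying},
    }
    lag_sources = {src: name for src, name in lag_sources.items() if src in df.columns}

    g = df.groupby(idc, sort=False)
    same_person = g[wc].shift(1).notna() & (df[wc] - g[wc].shift(1) == 1)
    for src, name in lag_sources.items():
        shifted = g[src].shift(1)
        df[name] = shifted.where(same_person)

    out = df.loc[same_person.to_numpy()].reset_index(drop=True)
    out["age_sq"] = out["age"].astype(float) ** 2
    for key in ("poverty_line", "poverty_median_source"):
        if key in panel.attrs:
            out.attrs[key] = panel.attrs[key]
    return out
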