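"""Weighted pooled logistic outcome model and marginal (standardised) effects.

The outcome model is a logistic regression over stacked person-wave rows,
maximising the weight-multiplied Bernoulli log-likelihood by iteratively
reweighted least squares.  Combined with inverse-probability-of-treatment
weights and the full covariate adjustment set it forms a double-robust
estimator: the marginal contrast is consistent if either the weight model
or the outcome model is correctly specified.

Marginal quantities are obtained by g-computation over the analysis
sample: every row is predicted twice with the exposure forced to each
level (other columns at observed values), predictions are weight-averaged
into marginal risks, and the odds ratio, absolute risk difference (in
percentage points) and population attributable fraction follow from those
risks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr as _qr

__all__ = [
    "FitResult",
    "MarginalEstimates",
    "SeparationError",
    "RankDeficiencyError",
    "weighted_logistic",
    "predict_proba",
    "marginal_standardise",
    "paf",
]


class SeparationError(RuntimeError):
    """The likelihood has no finite maximiser (perfect or quasi-separation)."""


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient; names the aliased columns."""


@dataclass
class FitResult:
    """Coefficients and convergence diagnostics of a weighted logistic fit."""

    params: np.ndarray
    names: list[str]
    converged: bool
    n_iter: int
    gradient_norm: float
    loglike: float

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "params": {n: float(b) for n, b in zip(self.names, self.params)},
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "gradient_norm": float(self.gradient_norm),
            "loglike": float(self.loglike),
        }


@dataclass
class MarginalEstimates:
    """Standardised risks and the marginal contrasts derived from them."""

    risk_exposed: float
    risk_unexposed: float
    odds_ratio: float
    risk_difference_pp: float
    prevalence_unexposed_pp: float
    paf_pct: float
    paf_pct_standardised: float = field(default=float("nan"))
    prevalence_total_pp: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # pivoted QR flags which columns are linear combinations of earlier ones
    if X.shape[1] == 0:
        return
    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[j]] for j in range(len(diag)) if diag[j] <= tol]
    if bad:
        raise RankDeficiencyError(f"design is rank deficient; aliased columns: {bad}")


def weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    names: list[str] | None = None,
    *,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    check_rank: bool = True,
) -> FitResult:
    """Maximum-likelihood weighted logistic regression via IRLS (Newton).

    ``w`` multiplies each observation's log-likelihood contribution; the
    fit is invariant to rescaling all weights by a constant.  Convergence
    is declared when the per-unit-weight score norm drops below ``tol``.
    Separation is reported as an error rather than silently returning
    divergent coefficients.  ``start`` allows warm starting (used heavily
    by the bootstrap); with a good start one or two Newton steps suffice.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if w is None:
        w = np.ones(n)
    else:
        w = np.asarray(w, dtype=np.float64)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    names = names or [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("names length must match design columns")
    if check_rank:
        _check_rank(X * np.sqrt(w)[:, None], names)
    if y.min() == y.max():
        raise SeparationError("outcome is constant; the intercept diverges")

    wsum = w.sum()
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=np.float64).copy()
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _expit(eta)
        grad = X.T @ (w * (y - mu))
        grad_norm = float(np.max(np.abs(grad)) / wsum)
        if grad_norm < tol:
            break
        irls_w = w * mu * (1.0 - mu)
        # guard against collapse of the working weights under separation
        if irls_w.max() < 1e-12:
            raise SeparationError("working weights collapsed; data are separated")
        H = (X * irls_w[:, None]).T @ X
        H[np.diag_indices_from(H)] += 1e-10 * wsum
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise RankDeficiencyError(str(exc)) from exc
        # dampen absurd steps (a symptom of separation)
        step_max = np.max(np.abs(step))
        if step_max > 10.0:
            step *= 10.0 / step_max
        beta += step
        if np.max(np.abs(beta)) > 40.0:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"coefficient for {names[j]!r} is diverging (|beta| > 40); "
                "perfect or quasi-separation"
            )
    eta = X @ beta
    mu = _expit(eta)
    eps = 1e-12
    ll = float(np.sum(w * (y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps))))
    converged = grad_norm < tol
    if converged and np.max(np.abs(beta)) > 15.0 and max_iter >= 25:
        # a flat likelihood with a huge coefficient is quasi-separation:
        # the score vanishes while the MLE runs off to infinity
        j = int(np.argmax(np.abs(beta)))
        raise SeparationError(
            f"coefficient for {names[j]!r} is {beta[j]:.1f}; quasi-separation"
        )
    if not converged and max_iter >= 25:
        raise SeparationError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(score norm {grad_norm:.3e}); last coefficients {dict(zip(names, beta))}"
        )
    return FitResult(beta, list(names), converged, it, grad_norm, ll)


def predict_proba(fit: FitResult, X: np.ndarray) -> np.ndarray:
    return _expit(np.asarray(X, dtype=np.float64) @ fit.params)


def paf(prev_total: float, prev_unexposed: float) -> float:
    """Population attributable fraction, in percent.

    100 x (prevalence in total population - prevalence in unexposed) /
    prevalence in total population.  Negative for protective exposures.
    """
    if prev_total <= 0:
        raise ValueError("total prevalence must be positive")
    return 100.0 * (prev_total - prev_unexposed) / prev_total


def marginal_standardise(
    fit: FitResult,
    X: np.ndarray,
    exposure_name: str,
    w: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> MarginalEstimates:
    """G-computation of marginal risks with the exposure forced to 1 and 0.

    All other design columns — including mediator columns in a controlled
    direct-effect model — stay at their observed values, so the direct
    effect contrast holds the mediator at its natural value.  Risks are
    averaged with the supplied weights.  If ``y`` is given, the observed
    (weighted) outcome prevalence feeds the attributable-fraction
    computation alongside the model-standardised total prevalence.
    """
    X = np.asarray(X, dtype=np.float64)
    if exposure_name not in fit.names:
        raise ValueError(f"exposure column {exposure_name!r} not in the fitted design")
    j = fit.names.index(exposure_name)
    w = np.ones(X.shape[0]) if w is None else np.asarray(w, dtype=np.float64)
    wsum = w.sum()

    # forcing a binary exposure column only shifts the linear predictor by
    # beta_j, so both counterfactual predictions come from one matvec
    a_obs = X[:, j]
    beta_j = fit.params[j]
    eta = X @ fit.params
    p1 = _expit(eta + (1.0 - a_obs) * beta_j)
    p0 = _expit(eta - a_obs * beta_j)
    r1 = float(np.sum(w * p1) / wsum)
    r0 = float(np.sum(w * p0) / wsum)

    odds_ratio = (r1 / (1 - r1)) / (r0 / (1 - r0))
    rd_pp = 100.0 * (r1 - r0)

    prev_total_std = float(np.sum(w * (a_obs * p1 + (1 - a_obs) * p0)) / wsum)
    if y is not None:
        prev_total = float(np.sum(w * np.asarray(y, dtype=np.float64)) / wsum)
    else:
        prev_total = prev_total_std
    return MarginalEstimates(
        risk_exposed=r1,
        risk_unexposed=r0,
        odds_ratio=float(odds_ratio),
        risk_difference_pp=rd_pp,
        prevalence_unexposed_pp=100.0 * r0,
        paf_pct=paf(prev_total, r0),
        paf_pct_standardised=paf(prev_total_std, r0),
        prevalence_total_pp=100.0 * prev_total,
    )
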