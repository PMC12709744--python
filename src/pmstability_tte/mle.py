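"""Maximum-likelihood estimation of the exponential regression.

This is the package's internal oracle for the information decomposition —
on data simulated at the true parameters, the inverse observed information
of the fit converges to n^{-1} I^{-1} — and the engine for post-fit
uncertainty intervals on observed cohorts.

The log-likelihood with event indicator d_i and follow-up t_i is

    l(beta) = sum_i [ d_i * mu_i - t_i * exp(mu_i) ],   mu_i = x_i beta,

with score X'(d - t exp(mu)) and observed information
X' diag(t exp(mu)) X.  Newton-Raphson with step-halving starts from the
intercept-only closed form alpha0 = ln(events / person-years), the exact
null MLE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .cohort import Cohort
from .errors import FitError, StateError
from .precision import uncertainty_interval

__all__ = ["MLEFit", "fit_exponential_mle", "postfit_intervals"]

_SCORE_TOL = 1e-8
_MAX_ITER = 100


@dataclass(frozen=True)
class MLEFit:
    """Converged exponential-regression fit."""

    coefficients: np.ndarray
    names: tuple[str, ...]
    observed_information: np.ndarray
    covariance: np.ndarray
    loglik: float
    converged: bool
    iterations: int
    n: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "names": list(self.names),
                    "coefficients": self.coefficients.tolist(),
                    "covariance": self.covariance.tolist(),
                    "loglik": self.loglik,
                    "converged": self.converged,
                    "iterations": self.iterations,
                    "n": self.n,
                },
                indent=2,
            ),
            encoding="utf-8",
        )


def _design(cohort: Cohort, columns: tuple[str, ...] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = tuple(columns) if columns is not None else tuple(cohort.predictors.columns)
    X = np.column_stack(
        [np.ones(cohort.n)] + [cohort.predictors[c].to_numpy(float) for c in cols]
    )
    return X, ("(intercept)",) + cols


def fit_exponential_mle(
    cohort: Cohort, columns: tuple[str, ...] | None = None
) -> MLEFit:
    """Newton-Raphson MLE of the exponential regression on an observed
    cohort (all predictor columns by default).

    Convergence: max |score| < 1e-8 within 100 iterations, with
    step-halving whenever a full Newton step would decrease the
    log-likelihood.  Raises :class:`FitError` for no events, a
    rank-deficient design, or non-convergence.
    """
    if not cohort.has_followup:
        raise StateError("MLE needs follow-up columns")
    X, names = _design(cohort, columns)
    d = cohort.event
    t = cohort.time
    events = float(d.sum())
    if events == 0:
        raise FitError("no events observed: the exponential likelihood is unbounded")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is rank deficient")

    def loglik(beta: np.ndarray) -> float:
        mu = X @ beta
        return float(d @ mu - t @ np.exp(mu))

    beta = np.zeros(X.shape[1])
    beta[0] = np.log(events / t.sum())
    ll = loglik(beta)
    trace = [ll]
    converged = False
    iterations = 0
    for iterations in range(1, _MAX_ITER + 1):
        mu = X @ beta
        lam = t * np.exp(mu)
        score = X.T @ (d - lam)
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            iterations -= 1
            break
        H = (X * lam[:, None]).T @ X
        try:
            step = cho_solve(cho_factor(H), score)
        except np.linalg.LinAlgError as exc:
            raise FitError("observed information not positive definite during fit") from exc
        scale = 1.0
        for _ in range(40):  # step-halving keeps the log-likelihood non-decreasing
            new_beta = beta + scale * step
            new_ll = loglik(new_beta)
            if new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise FitError(f"step-halving failed at iteration {iterations}; trace={trace}")
        beta, ll = new_beta, new_ll
        trace.append(ll)
    if not converged:
        mu = X @ beta
        score = X.T @ (d - t * np.exp(mu))
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
    if not converged:
        raise FitError(
            f"Newton-Raphson did not converge in {_MAX_ITER} iterations; "
            f"log-likelihood trace={trace[-5:]}"
        )
    lam = t * np.exp(X @ beta)
    H = (X * lam[:, None]).T @ X
    covariance = cho_solve(cho_factor(H), np.eye(X.shape[1]))
    covariance = 0.5 * (covariance + covariance.T)
    return MLEFit(
        coefficients=beta,
        names=names,
        observed_information=H,
        covariance=covariance,
        loglik=ll,
        converged=True,
        iterations=iterations,
        n=cohort.n,
    )


def postfit_intervals(
    fit: MLEFit, cohort: Cohort, t: float, level: float = 0.95
) -> pd.DataFrame:
    """Per-individual risk-scale uncertainty intervals from a converged fit:
    var(mu_hat_i) = x_i cov x_i' mapped through the risk function at the
    fitted linear predictor."""
    if not fit.converged:
        raise FitError("fit did not converge")
    X, _ = _design(cohort, tuple(fit.names[1:]))
    mu_hat = X @ fit.coefficients
    var_mu = np.einsum("ij,jk,ik->i", X, fit.covariance, X)
    lower, upper = uncertainty_interval(mu_hat, var_mu, t, level)
    risk_hat = 1.0 - np.exp(-np.exp(mu_hat) * t)
    return pd.DataFrame(
        {
            "id": np.asarray(cohort.ids),
            "mu_hat": mu_hat,
            "risk_hat": risk_hat,
            "var_mu": var_mu,
            "lower": lower,
            "upper": upper,
            "width": upper - lower,
        }
    )
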