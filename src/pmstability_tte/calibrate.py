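"""Iterative specification of the core model from a target C-index and
overall risk.

Given relative weights beta and a cohort carrying the joint predictor
distribution, find (alpha, delta) so that the exponential core model
attains a target concordance and a target mean event risk at the horizon.
Because the analytic (no-censoring) C-index depends only on differences of
linear predictors, it is free of alpha; the problem therefore splits into
two nested one-dimensional bracketed root finds:

1. outer: delta >= 0 such that C(delta) = target C (C(0) = 0.5 and C is
   non-decreasing in delta, so the root is unique when attainable);
2. inner: alpha such that mean_i F_i(t*) = target risk at that delta
   (mean risk is strictly increasing in alpha).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .cohort import Cohort, standardise
from .errors import CalibrationError
from .model import CoreModel, concordance_exponential, event_risk

__all__ = [
    "CalibrationTarget",
    "CalibrationResult",
    "calibrate",
    "standardised_equal_weight_model",
]

_DELTA_MAX = 64.0


@dataclass(frozen=True)
class CalibrationTarget:
    """Targets and tolerances for the (alpha, delta) search.

    Defaults reproduce three-decimal reporting of the calibrated pair.
    """

    target_c: float
    target_risk: float
    tol_c: float = 0.001
    tol_risk: float = 0.001
    max_iter: int = 200

    def __post_init__(self) -> None:
        if not (0.5 <= self.target_c < 1.0):
            raise ValueError("target_c must lie in [0.5, 1)")
        if not (0.0 < self.target_risk < 1.0):
            raise ValueError("target_risk must lie in (0, 1)")
        if self.tol_c <= 0 or self.tol_risk <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class CalibrationResult:
    model: CoreModel
    achieved_c: float
    achieved_risk: float
    c_evaluations: int
    risk_evaluations: int


def _solve_alpha(z: np.ndarray, delta: float, target: CalibrationTarget, horizon: float) -> tuple[float, int]:
    """Inner root find: alpha s.t. mean event risk at the horizon matches."""
    evals = 0

    def gap(alpha: float) -> float:
        nonlocal evals
        evals += 1
        return float(np.mean(event_risk(alpha + delta * z, horizon))) - target.target_risk

    lo, hi = -5.0, 5.0
    while gap(lo) > 0 and lo > -60:
        lo -= 10.0
    while gap(hi) < 0 and hi < 60:
        hi += 10.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError("target overall risk unreachable for any intercept")
    alpha = brentq(gap, lo, hi, xtol=1e-12, maxiter=target.max_iter)
    return float(alpha), evals


def calibrate(
    cohort: Cohort,
    weights: dict[str, float],
    target: CalibrationTarget,
    horizon: float,
) -> CalibrationResult:
    """Find (alpha, delta) matching the target C-index and overall risk.

    Returns the calibrated :class:`CoreModel` (carrying the cohort's
    standardisation constants for the weighted columns) together with the
    achieved C and mean risk and the number of function evaluations.
    Raises :class:`CalibrationError` when the target C cannot be reached on
    the delta bracket (e.g. a flat weighted linear predictor).
    """
    probe = CoreModel(alpha=0.0, delta=1.0, weights=weights, horizon=horizon)
    z = probe.weighted_score(cohort)
    if cohort.n < 2:
        raise CalibrationError("need at least two individuals")

    c_evals = 0

    def c_of(delta: float) -> float:
        nonlocal c_evals
        c_evals += 1
        return concordance_exponential(np.exp(delta * z))

    if target.target_c - 0.5 <= target.tol_c:
        delta = 0.0
    else:
        if float(np.ptp(z)) == 0.0:
            raise CalibrationError(
                "weighted linear predictor is constant; any C-index above 0.5 is unreachable"
            )
        hi = 1.0
        while c_of(hi) < target.target_c:
            hi *= 2.0
            if hi > _DELTA_MAX:
                raise CalibrationError(
                    f"target C-index {target.target_c} unreachable for delta in "
                    f"[0, {_DELTA_MAX}] (achieved {c_of(_DELTA_MAX):.4f} at the cap)"
                )
        delta = float(
            brentq(lambda d: c_of(d) - target.target_c, 0.0, hi, xtol=1e-8, maxiter=target.max_iter)
        )

    alpha, risk_evals = _solve_alpha(z, delta, target, horizon)

    standardisation = {
        name: (cohort.columns[name].mean, cohort.columns[name].sd)
        for name in weights
        if cohort.columns[name].standardised and cohort.columns[name].mean is not None
    }
    model = CoreModel(
        alpha=alpha,
        delta=delta,
        weights=dict(weights),
        horizon=horizon,
        standardisation=standardisation,
    )
    profile = model.linear_predictor(cohort)
    achieved_c = concordance_exponential(profile.eta)
    achieved_risk = float(np.mean(profile.risk))
    if abs(achieved_c - target.target_c) > target.tol_c:
        raise CalibrationError(
            f"C-index converged to {achieved_c:.5f}, outside tolerance of target {target.target_c}"
        )
    if abs(achieved_risk - target.target_risk) > target.tol_risk:
        raise CalibrationError(
            f"overall risk converged to {achieved_risk:.5f}, outside tolerance of "
            f"target {target.target_risk}"
        )
    return CalibrationResult(
        model=model,
        achieved_c=achieved_c,
        achieved_risk=achieved_risk,
        c_evaluations=c_evals,
        risk_evaluations=risk_evals,
    )


def standardised_equal_weight_model(
    cohort: Cohort,
    target: CalibrationTarget,
    horizon: float,
    zero_weight: tuple[str, ...] = (),
) -> CalibrationResult:
    """Equal-weight specification: standardise every continuous predictor,
    give all predictors weight 1 (a 1-SD increase carries the same
    predictive effect for each) and calibrate (alpha, delta).

    Columns named in ``zero_weight`` (e.g. protected characteristics kept
    only for fairness checks) get weight 0 and do not drive the C-index.
    """
    to_std = [
        name
        for name, info in cohort.columns.items()
        if info.kind == "continuous" and not info.standardised
    ]
    if to_std:
        cohort = standardise(cohort, to_std)
    weights = {
        name: 0.0 if name in zero_weight else 1.0 for name in cohort.predictors.columns
    }
    return calibrate(cohort, weights, target, horizon)
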