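"""Instability summary statistics: misclassification probabilities against a
risk threshold, MAPE/RMSPE from uncertainty-distribution draws, and grouped
(fairness) summaries.

The misclassification probability is the mass of an individual's risk
uncertainty distribution on the opposite side of the clinical threshold
from their true risk.  Because the risk map is monotone in mu, a threshold
p* corresponds to mu* = ln(-ln(1-p*)/t*), and with mu_hat ~ N(mu, var) the
analytic value is Phi(-|mu - mu*| / sqrt(var)) — exact, deterministic, and
the limit of the paper-style sampling construction, which is retained as a
Monte-Carlo cross-check mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import SchemaError
from .model import event_risk, mu_for_risk
from .precision import sample_uncertainty_distribution

__all__ = [
    "ThresholdSpec",
    "misclassification_probability",
    "prediction_error",
    "mape",
    "rmspe",
    "attach_metrics",
    "summarise_instability",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Clinical risk threshold p* at horizon t* (years)."""

    threshold: float
    horizon: float

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @property
    def mu_star(self) -> float:
        return float(mu_for_risk(self.threshold, self.horizon))


def misclassification_probability(
    mu_true,
    var_mu,
    spec: ThresholdSpec,
    method: str = "analytic",
    draws: int = 100_000,
    seed: int | np.random.Generator = 0,
):
    """Probability that the uncertainty distribution falls on the opposite
    side of the threshold from the true risk.

    Analytic mode: Phi(-|mu - mu*|/sqrt(var)); exactly 0.5 when the true
    risk sits on the threshold (including the degenerate var=0 boundary).
    Monte-Carlo mode: the fraction of sampled risks beyond the threshold.
    Vectorised over ``mu_true``/``var_mu``.
    """
    mu_true = np.asarray(mu_true, float)
    var_mu = np.asarray(var_mu, float)
    if np.any(var_mu < 0):
        raise ValueError("var_mu must be non-negative")
    gap = np.abs(mu_true - spec.mu_star)
    if method == "analytic":
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var_mu > 0, gap / np.sqrt(np.maximum(var_mu, 1e-300)), np.inf)
        out = norm.sf(z)
        # at the boundary (true risk exactly on the threshold) the symmetric limit is 1/2
        out = np.where(gap == 0.0, 0.5, out)
        return float(out) if out.ndim == 0 else out
    if method == "monte-carlo":
        risks = sample_uncertainty_distribution(mu_true, var_mu, spec.horizon, draws, seed)
        true_risk = event_risk(mu_true, spec.horizon)
        above = np.asarray(true_risk) > spec.threshold
        opposite = np.where(
            np.atleast_1d(above)[..., None], risks <= spec.threshold, risks > spec.threshold
        )
        out = opposite.mean(axis=-1)
        out = np.where(np.atleast_1d(np.asarray(true_risk) == spec.threshold), 0.5, out)
        return float(out[0]) if mu_true.ndim == 0 else out
    raise ValueError(f"unknown method {method!r}")


def prediction_error(
    mu_true, var_mu, t: float, draws: int = 1000, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """(MAPE, RMSPE) per individual from seeded uncertainty-distribution
    draws: mean absolute and root-mean-squared difference between sampled
    risks and the individual's true risk."""
    mu_arr = np.asarray(mu_true, float)
    risks = sample_uncertainty_distribution(mu_true, var_mu, t, draws, seed)
    diff = risks - event_risk(mu_arr, t)[..., None]
    return np.abs(diff).mean(axis=-1), np.sqrt((diff**2).mean(axis=-1))


def mape(mu_true, var_mu, t: float, draws: int = 1000, seed: int | np.random.Generator = 0):
    """Mean absolute prediction error of the risk uncertainty distribution."""
    return prediction_error(mu_true, var_mu, t, draws, seed)[0]


def rmspe(mu_true, var_mu, t: float, draws: int = 1000, seed: int | np.random.Generator = 0):
    """Root-mean-squared prediction error of the risk uncertainty distribution."""
    return prediction_error(mu_true, var_mu, t, draws, seed)[1]


def attach_metrics(
    records: pd.DataFrame,
    spec: ThresholdSpec,
    draws: int = 1000,
    seed: int = 0,
    method: str = "analytic",
) -> pd.DataFrame:
    """Add mape, rmspe and misclassification columns to a precision-record
    frame (requires mu_true and var_mu columns)."""
    out = records.copy()
    m, r = prediction_error(
        records["mu_true"].to_numpy(), records["var_mu"].to_numpy(), spec.horizon, draws, seed
    )
    out["mape"] = m
    out["rmspe"] = r
    out["misclassification"] = misclassification_probability(
        records["mu_true"].to_numpy(),
        records["var_mu"].to_numpy(),
        spec,
        method=method,
        seed=seed,
    )
    return out


_STATS = ("width", "mape", "rmspe", "misclassification")


def _stat_row(group: str, df: pd.DataFrame) -> dict:
    row: dict = {"group": group, "n_individuals": len(df)}
    for stat in _STATS:
        if stat not in df.columns:
            continue
        x = df[stat].to_numpy(float)
        row[f"{stat}_mean"] = float(x.mean())
        row[f"{stat}_min"] = float(x.min())
        row[f"{stat}_median"] = float(np.median(x))
        row[f"{stat}_max"] = float(x.max())
    return row


def summarise_instability(
    records: pd.DataFrame, by: str | None = None
) -> pd.DataFrame:
    """Mean/min/median/max of interval width, MAPE, RMSPE and
    misclassification — overall and, when ``by`` names a column of
    ``records``, per subgroup."""
    if records.empty:
        raise ValueError("no records to summarise")
    rows = [_stat_row("all", records)]
    if by is not None:
        if by not in records.columns:
            raise SchemaError(f"no subgroup column named {by!r} in records")
        for label, df in records.groupby(by, sort=True):
            rows.append(_stat_row(str(label), df))
    return pd.DataFrame(rows)
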