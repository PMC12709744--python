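"""Per-individual prediction variance, risk-scale uncertainty intervals and
required-sample-size inversion.

Option A (given n): the variance of a new individual's estimated linear
predictor is var(mu_hat) = n^{-1} x I^{-1} x'; a level-(1-a) interval
mu +/- z*sqrt(var) maps monotonically to the risk scale through
F(t) = 1 - exp(-exp(mu) t), giving an interval guaranteed to contain the
individual's true risk by construction.

Option B (given precision): risk-band width targets are inverted to
variance targets (unique root, width strictly increasing in the standard
deviation), and n = x I^{-1} x' / var_target per individual; the cohort
recommendation is the ceiling of the maximum over the target individuals,
the only combining rule that guarantees the width target for all of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .cohort import Cohort
from .errors import StateError
from .information import UnitInformation
from .model import CoreModel, event_risk, mu_for_risk

__all__ = [
    "SampleSizeSpec",
    "RequiredN",
    "prediction_variance",
    "uncertainty_interval",
    "sample_uncertainty_distribution",
    "required_variance_for_width",
    "required_n",
    "cohort_required_n",
    "precision_records",
]

DEFAULT_BANDS = (0.01, 0.025, 0.05, 0.10, 0.15, 0.20)


def prediction_variance(info: UnitInformation, x_new: np.ndarray, n: int | float):
    """var(mu_hat_new) = n^{-1} x_new I^{-1} x_new'.

    ``x_new`` is one design row (1, x_1, ..., x_P) or a matrix of rows;
    returns a scalar or a vector accordingly.  Scales exactly as 1/n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    x = np.asarray(x_new, float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != info.inverse.shape[0]:
        raise ValueError(
            f"x_new has {x.shape[1]} entries but the information matrix is "
            f"{info.inverse.shape[0]}x{info.inverse.shape[0]}"
        )
    v = np.einsum("ij,jk,ik->i", x, info.inverse, x) / n
    return float(v[0]) if single else v


def uncertainty_interval(mu_true, var_mu, t: float, level: float = 0.95):
    """Risk-scale uncertainty interval at time t.

    The mu-scale interval mu +/- z*sqrt(var_mu) is mapped through the
    (strictly increasing) risk function; the result always contains the
    true risk F(mu, t).  Vectorised over ``mu_true``/``var_mu``; returns
    (lower, upper).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    mu_true = np.asarray(mu_true, float)
    var_mu = np.asarray(var_mu, float)
    if np.any(var_mu < 0):
        raise ValueError("var_mu must be non-negative")
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var_mu)
    return event_risk(mu_true - half, t), event_risk(mu_true + half, t)


def sample_uncertainty_distribution(
    mu_true, var_mu, t: float, draws: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draws from an individual's risk uncertainty distribution.

    Samples mu_hat ~ N(mu_true, var_mu) and maps through the risk function;
    per individual this is marginally identical to sampling the parameter
    vector jointly from N(beta, var(beta_hat)) and scoring, because
    x_new beta_hat is then exactly N(mu_true, x_new var(beta_hat) x_new').
    Vectorised: scalar inputs give shape (draws,), vector inputs of length
    m give shape (m, draws).
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    mu_true = np.asarray(mu_true, float)
    var_mu = np.asarray(var_mu, float)
    if mu_true.ndim == 0:
        z = rng.standard_normal(draws)
        return event_risk(mu_true + np.sqrt(var_mu) * z, t)
    z = rng.standard_normal((mu_true.size, draws))
    return event_risk(mu_true[:, None] + np.sqrt(var_mu)[:, None] * z, t)


def required_variance_for_width(
    risk_band: float, target_width: float, t: float, level: float = 0.95
) -> float:
    """Variance of mu_hat giving a risk-scale interval of the target width
    at an individual whose true risk equals ``risk_band``.

    The width is strictly increasing in the mu-scale standard deviation s
    (from 0 towards 1), so the root is unique; solved by bracketed root
    finding to 1e-10 on the width.
    """
    if not 0.0 < target_width < 1.0:
        raise ValueError("target width must lie strictly inside (0, 1)")
    mu = float(mu_for_risk(risk_band, t))

    def width(s: float) -> float:
        lo, hi = uncertainty_interval(mu, s * s, t, level)
        return float(hi - lo)

    hi_s = 1.0
    while width(hi_s) < target_width:
        hi_s *= 2.0
        if hi_s > 1e6:  # width -> 1 as s -> inf, so this cannot trigger for valid targets
            raise ValueError(f"target width {target_width} unattainable")
    s = brentq(lambda s: width(s) - target_width, 0.0, hi_s, xtol=1e-12)
    return float(s * s)


class RequiredN(NamedTuple):
    """Raw (real-valued) and integer (rounded-up) required sample size."""

    raw: float
    rounded: int


def required_n(info: UnitInformation, x_new: np.ndarray, var_target: float) -> RequiredN:
    """Sample size so that var(mu_hat_new) equals ``var_target``:
    n = x_new I^{-1} x_new' / var_target."""
    if var_target <= 0:
        raise ValueError("var_target must be positive")
    quad = prediction_variance(info, x_new, 1.0)  # x I^{-1} x'
    raw = quad / var_target
    return RequiredN(raw=float(raw), rounded=int(math.ceil(raw)))


@dataclass(frozen=True)
class SampleSizeSpec:
    """Risk bands and per-band maximum 95% interval width targets.

    Each individual is assigned the band closest to their true risk (ties
    to the lower band) and the band's width target is converted to a
    variance target at the band's risk value.
    """

    bands: tuple[float, ...] = DEFAULT_BANDS
    target_widths: tuple[float, ...] = (0.2,) * len(DEFAULT_BANDS)
    level: float = 0.95

    def __post_init__(self) -> None:
        b = np.asarray(self.bands, float)
        if len(self.bands) != len(self.target_widths):
            raise ValueError("bands and target_widths differ in length")
        if np.any((b <= 0) | (b >= 1)) or np.any(np.diff(b) <= 0):
            raise ValueError("bands must be strictly increasing inside (0, 1)")
        w = np.asarray(self.target_widths, float)
        if np.any((w <= 0) | (w >= 1)):
            raise ValueError("target widths must lie strictly inside (0, 1)")

    @classmethod
    def uniform_width(cls, width: float, bands: tuple[float, ...] = DEFAULT_BANDS, level: float = 0.95):
        return cls(bands=bands, target_widths=(width,) * len(bands), level=level)

    def assign_bands(self, risk: np.ndarray) -> np.ndarray:
        """Index of the band closest to each true risk; ties go to the
        lower band (argmin picks the first of equal distances)."""
        risk = np.asarray(risk, float)
        return np.argmin(np.abs(risk[:, None] - np.asarray(self.bands)[None, :]), axis=1)

    def variance_targets(self, t: float) -> np.ndarray:
        return np.array(
            [
                required_variance_for_width(b, w, t, self.level)
                for b, w in zip(self.bands, self.target_widths)
            ]
        )


def cohort_required_n(
    info: UnitInformation,
    cohort: Cohort,
    model: CoreModel,
    spec: SampleSizeSpec,
    subset: np.ndarray | Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Per-individual and overall required sample size (Option B).

    Returns (records, overall_n): ``records`` has one row per individual
    with their true risk, assigned band, variance target and raw required
    n; ``overall_n`` is the ceiling of the maximum raw n over the subset
    (all individuals when ``subset`` is None).  ``subset`` may be a boolean
    mask or a callable evaluated on the records frame (e.g.
    ``lambda r: r.risk_true <= 0.3``).
    """
    profile = model.linear_predictor(cohort)
    X = model.design_matrix(cohort)
    band_idx = spec.assign_bands(profile.risk)
    var_targets = spec.variance_targets(model.horizon)[band_idx]
    quad = prediction_variance(info, X, 1.0)
    raw_n = quad / var_targets
    records = pd.DataFrame(
        {
            "id": np.asarray(cohort.ids),
            "risk_true": profile.risk,
            "band": np.asarray(spec.bands)[band_idx],
            "target_width": np.asarray(spec.target_widths)[band_idx],
            "var_target": var_targets,
            "n_required": raw_n,
        }
    )
    if subset is None:
        mask = np.ones(len(records), bool)
    elif callable(subset):
        mask = np.asarray(subset(records), bool)
    else:
        mask = np.asarray(subset, bool)
    if not mask.any():
        raise StateError("required-n subset selects no individuals")
    overall = int(math.ceil(float(records.loc[mask, "n_required"].max())))
    return records, overall


def precision_records(
    cohort: Cohort,
    model: CoreModel,
    info: UnitInformation,
    n: int | float,
    level: float = 0.95,
) -> pd.DataFrame:
    """One row per individual: true linear predictor and risk, var(mu_hat)
    at development size n, risk-scale interval and its width (Option A)."""
    profile = model.linear_predictor(cohort)
    X = model.design_matrix(cohort)
    var_mu = prediction_variance(info, X, n)
    lower, upper = uncertainty_interval(profile.mu, var_mu, model.horizon, level)
    return pd.DataFrame(
        {
            "id": np.asarray(cohort.ids),
            "mu_true": profile.mu,
            "risk_true": profile.risk,
            "var_mu": var_mu,
            "lower": lower,
            "upper": upper,
            "width": upper - lower,
        }
    )
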