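"""Event-time and censoring-time generation, and synthetic fixture cohorts.

Event times come from the core model by inverse-CDF sampling
(t_i = -ln(U_i)/eta_i).  Censoring is independent of predictors and event
times and follows one of four declared schemes: none, constant-rate
exponential, a window scheme (no censoring before t_min, uniform censoring
on [t_min, t_max], administrative cut at t_max) and pure administrative
censoring at a fixed time.  Observed follow-up is the minimum of the two
times with ties resolved as events.

The fixture generator emulates a breast-cancer-like cohort: correlated
continuous predictors via a Gaussian copula, independent categorical draws,
a core model calibrated to a target C-index and overall risk, and follow-up
assembled from the chosen censoring scheme.  Every stochastic operation
takes an explicit seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibrate import CalibrationResult, CalibrationTarget, calibrate
from .cohort import Cohort, ColumnInfo, standardise
from .errors import ValidationError
from .model import CoreModel

__all__ = [
    "NoCensoring",
    "ExponentialCensoring",
    "WindowCensoring",
    "AdministrativeCensoring",
    "ContinuousSpec",
    "CategoricalSpec",
    "FixtureSpec",
    "Fixture",
    "simulate_event_times",
    "simulate_censoring",
    "assemble_followup",
    "with_simulated_followup",
    "generate_fixture",
    "gbsg_like",
]


# -- censoring schemes ---------------------------------------------------


@dataclass(frozen=True)
class NoCensoring:
    """Every event is observed (censoring time +inf)."""

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, np.inf)


@dataclass(frozen=True)
class ExponentialCensoring:
    """Constant censoring rate per year."""

    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("censoring rate must be positive")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return -np.log1p(-rng.random(n)) / self.rate


@dataclass(frozen=True)
class WindowCensoring:
    """No censoring before ``t_min``; censoring times uniform on
    [t_min, t_max] for a fraction ``p_uniform`` of individuals; everyone
    else administratively censored at ``t_max``."""

    t_min: float
    t_max: float
    p_uniform: float = 1.0

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("need t_min < t_max")
        if not 0.0 <= self.p_uniform <= 1.0:
            raise ValueError("p_uniform must lie in [0, 1]")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        uniform_draw = self.t_min + (self.t_max - self.t_min) * rng.random(n)
        return np.where(u < self.p_uniform, uniform_draw, self.t_max)


@dataclass(frozen=True)
class AdministrativeCensoring:
    """All remaining individuals censored at a fixed maximum follow-up."""

    t_max: float

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, float(self.t_max))


CensoringScheme = NoCensoring | ExponentialCensoring | WindowCensoring | AdministrativeCensoring


# -- simulation ----------------------------------------------------------


def simulate_event_times(
    model: CoreModel, cohort: Cohort, seed: int | np.random.Generator
) -> np.ndarray:
    """One exponential event time per individual, t_i = -ln(U_i)/eta_i."""
    rng = np.random.default_rng(seed)
    eta = model.linear_predictor(cohort).eta
    u = 1.0 - rng.random(cohort.n)  # in (0, 1]; keeps times finite
    return -np.log(u) / eta


def simulate_censoring(
    scheme: CensoringScheme, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """n censoring times from the declared scheme."""
    return scheme.draw(n, np.random.default_rng(seed))


def assemble_followup(
    event_times: np.ndarray, censoring_times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Observed follow-up: time = min(event, censoring), indicator 1 iff
    the event was observed (ties count as events)."""
    event_times = np.asarray(event_times, float)
    censoring_times = np.asarray(censoring_times, float)
    if event_times.shape != censoring_times.shape:
        raise ValidationError("event and censoring time vectors differ in length")
    time = np.minimum(event_times, censoring_times)
    event = (event_times <= censoring_times).astype(float)
    return time, event


def with_simulated_followup(
    cohort: Cohort, model: CoreModel, scheme: CensoringScheme, seed: int
) -> Cohort:
    """Attach simulated follow-up (events from the core model, censoring
    from the scheme) to a cohort without observed times."""
    ev_seed, cen_seed = np.random.SeedSequence(seed).spawn(2)
    t_event = simulate_event_times(model, cohort, np.random.default_rng(ev_seed))
    t_cens = simulate_censoring(scheme, cohort.n, np.random.default_rng(cen_seed))
    time, event = assemble_followup(t_event, t_cens)
    return cohort.with_followup(time, event)


# -- fixture cohorts -----------------------------------------------------


@dataclass(frozen=True)
class ContinuousSpec:
    """Marginal of one continuous predictor in the Gaussian copula.

    ``dist='normal'`` gives mean + sd * Z; ``dist='lognormal'`` exponentiates
    a N(mean, sd) log-scale draw.  ``integer`` rounds, ``minimum`` clips.
    """

    name: str
    mean: float
    sd: float
    dist: str = "normal"
    integer: bool = False
    minimum: float | None = None

    def transform(self, z: np.ndarray) -> np.ndarray:
        if self.dist == "normal":
            x = self.mean + self.sd * z
        elif self.dist == "lognormal":
            x = np.exp(self.mean + self.sd * z)
        else:
            raise ValueError(f"unknown marginal {self.dist!r}")
        if self.integer:
            x = np.round(x)
        if self.minimum is not None:
            x = np.maximum(x, self.minimum)
        return x


@dataclass(frozen=True)
class CategoricalSpec:
    """One independent categorical predictor with declared level
    probabilities and reference level (dummy-coded against it)."""

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]
    reference: str

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probs):
            raise ValueError("levels and probs differ in length")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("level probabilities must sum to 1")
        if self.reference not in self.levels:
            raise ValueError("reference level must be among the levels")


@dataclass(frozen=True)
class FixtureSpec:
    """Full recipe for a synthetic cohort: marginals, copula correlation,
    relative weights, calibration target, horizon, censoring and seed."""

    n: int
    continuous: tuple[ContinuousSpec, ...]
    categorical: tuple[CategoricalSpec, ...]
    weights: dict[str, float]
    target: CalibrationTarget
    horizon: float
    censoring: CensoringScheme
    correlation: np.ndarray | None = None
    seed: int = 0


@dataclass(frozen=True)
class Fixture:
    """Output of :func:`generate_fixture`: the cohort is the primary
    artefact; the calibrated core model and calibration diagnostics ride
    along because every downstream step needs them."""

    cohort: Cohort
    model: CoreModel
    calibration: CalibrationResult


def generate_fixture(spec: FixtureSpec, seed: int | None = None) -> Fixture:
    """Generate a seeded synthetic cohort with simulated follow-up.

    Continuous predictors are drawn jointly from a Gaussian copula with the
    spec's correlation matrix (identity if omitted), categorical predictors
    independently from their level probabilities.  Continuous predictors
    are then standardised, the core model calibrated to the target (C-index,
    overall risk) and follow-up simulated under the censoring scheme.
    """
    seed = spec.seed if seed is None else seed
    pred_seed, fu_seed = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(pred_seed)

    k = len(spec.continuous)
    if spec.correlation is None:
        corr = np.eye(k)
    else:
        corr = np.asarray(spec.correlation, float)
        if corr.shape != (k, k):
            raise ValueError("correlation matrix shape does not match continuous specs")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc

    z = rng.standard_normal((spec.n, k)) @ chol.T
    pred: dict[str, np.ndarray] = {}
    meta: dict[str, ColumnInfo] = {}
    for j, cs in enumerate(spec.continuous):
        pred[cs.name] = cs.transform(z[:, j])
        meta[cs.name] = ColumnInfo(name=cs.name, kind="continuous")

    subgroups: dict[str, np.ndarray] = {}
    for cat in spec.categorical:
        labels = rng.choice(cat.levels, size=spec.n, p=cat.probs)
        subgroups[cat.name] = labels
        for level in cat.levels:
            if level == cat.reference:
                continue
            name = f"{cat.name}_{level}"
            pred[name] = (labels == level).astype(float)
            meta[name] = ColumnInfo(name=name, kind="dummy")

    cohort = Cohort(
        predictors=pd.DataFrame(pred),
        columns=meta,
        subgroups=pd.DataFrame(subgroups) if subgroups else None,
    )
    cohort = standardise(cohort, [cs.name for cs in spec.continuous])

    calibration = calibrate(cohort, spec.weights, spec.target, spec.horizon)
    cohort = with_simulated_followup(
        cohort, calibration.model, spec.censoring, int(fu_seed.generate_state(1)[0] % 2**31)
    )
    return Fixture(cohort=cohort, model=calibration.model, calibration=calibration)


def gbsg_like(n: int = 10_000, seed: int = 0) -> FixtureSpec:
    """Preset emulating a node-positive breast-cancer cohort.

    Five predictors / six model parameters: age and tumour size (normal
    marginals), number of positive nodes (rounded lognormal), menopausal
    status (26% pre-menopausal) and tumour grade (reference grade 1).
    Relative weights (-1, 0.5, 2 on the standardised continuous scale;
    3, 3, 4 for post-menopause, grade 2 and grade 3) are calibrated to a
    C-index of 0.70 and an overall 5-year risk of 0.39; censoring follows
    the window scheme (none before 2 years, uniform to the 7.28-year
    administrative maximum).
    """
    return FixtureSpec(
        n=n,
        continuous=(
            ContinuousSpec("age", 53.0, 10.0),
            ContinuousSpec("size", 30.0, 14.0, minimum=3.0),
            ContinuousSpec("nodes", 1.0, 0.9, dist="lognormal", integer=True, minimum=1.0),
        ),
        categorical=(
            CategoricalSpec("meno", ("pre", "post"), (0.26, 0.74), "pre"),
            CategoricalSpec("grade", ("1", "2", "3"), (0.07, 0.67, 0.26), "1"),
        ),
        correlation=np.array(
            [
                [1.0, 0.10, 0.05],
                [0.10, 1.0, 0.30],
                [0.05, 0.30, 1.0],
            ]
        ),
        weights={
            "age": -1.0,
            "size": 0.5,
            "nodes": 2.0,
            "meno_post": 3.0,
            "grade_2": 3.0,
            "grade_3": 4.0,
        },
        target=CalibrationTarget(target_c=0.70, target_risk=0.39),
        horizon=5.0,
        censoring=WindowCensoring(2.0, 7.28),
        seed=seed,
    )
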