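"""Fisher's unit information matrix for the exponential core model.

For the exponential regression with design rows x_i = (1, x_1i, ..., x_Pi)
and observed log follow-up y_i = ln(t_i), the per-participant (unit)
information is estimated by the sample mean

    I[j, k] = mean_i( x_ij * x_ik * w_i ),   w_i = exp(y_i + mu_i) = t_i * exp(mu_i),

with mu_i the linear predictor of the assumed-true core model.  The total
information for a development sample of size n is n * I, so the parameter
covariance is var(beta_hat) = n^{-1} I^{-1}.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .cohort import Cohort
from .errors import SingularInformationError, StateError
from .model import CoreModel

__all__ = ["UnitInformation", "unit_information", "parameter_covariance"]

_CONDITION_GUARD = 1e10


@dataclass(frozen=True)
class UnitInformation:
    """(P+1)x(P+1) unit information matrix, its inverse and diagnostics."""

    matrix: np.ndarray
    inverse: np.ndarray
    n_source: int
    condition: float
    names: tuple[str, ...]

    def to_json(self, path: str | Path, provenance: str | None = None) -> None:
        payload = {
            "names": list(self.names),
            "matrix": self.matrix.tolist(),
            "inverse": self.inverse.tolist(),
            "n_source": self.n_source,
            "condition": self.condition,
        }
        if provenance is not None:
            payload["provenance"] = provenance
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "UnitInformation":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            matrix=np.asarray(d["matrix"], float),
            inverse=np.asarray(d["inverse"], float),
            n_source=int(d["n_source"]),
            condition=float(d["condition"]),
            names=tuple(d["names"]),
        )


def provenance_hash(cohort: Cohort, model: CoreModel) -> str:
    """Short stable hash of the cohort values and model parameters."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(cohort.predictors.to_numpy(float)).tobytes())
    if cohort.has_followup:
        h.update(cohort.time.tobytes())
        h.update(cohort.event.tobytes())
    h.update(json.dumps(model.to_dict(), sort_keys=True).encode())
    return h.hexdigest()[:16]


def _suspect_columns(matrix: np.ndarray, names: tuple[str, ...]) -> list[str]:
    """Columns loading most on the near-null eigenvector."""
    vals, vecs = np.linalg.eigh(matrix)
    v = np.abs(vecs[:, 0])
    implicated = v >= 0.5 * v.max()
    return [names[j] for j in np.flatnonzero(implicated)]


def unit_information(
    cohort: Cohort, model: CoreModel, mu: np.ndarray | None = None
) -> UnitInformation:
    """Estimate the unit information matrix from a cohort with follow-up.

    ``mu`` defaults to the assumed-true core model's linear predictor;
    pass fitted values instead for post-fit interval work.  Raises
    :class:`SingularInformationError` when the matrix is numerically
    singular (condition number above 1e10), naming the implicated columns.
    """
    if not cohort.has_followup:
        raise StateError("unit information needs observed or simulated follow-up")
    X = model.design_matrix(cohort)
    n, p1 = X.shape
    if n <= p1:
        raise StateError(f"need more individuals ({n}) than parameters ({p1})")
    if mu is None:
        mu = model.linear_predictor(cohort).mu
    w = cohort.time * np.exp(np.asarray(mu, float))
    matrix = (X * w[:, None]).T @ X / n
    matrix = 0.5 * (matrix + matrix.T)  # enforce exact symmetry

    names = ("(intercept)",) + model.names
    condition = float(np.linalg.cond(matrix))
    if not np.isfinite(condition) or condition > _CONDITION_GUARD:
        raise SingularInformationError(
            f"unit information is singular or near-singular (condition {condition:.3g}); "
            f"implicated columns: {_suspect_columns(matrix, names)}"
        )
    try:
        factor = cho_factor(matrix)
    except np.linalg.LinAlgError as exc:
        raise SingularInformationError(
            f"unit information is not positive definite; implicated columns: "
            f"{_suspect_columns(matrix, names)}"
        ) from exc
    inverse = cho_solve(factor, np.eye(p1))
    inverse = 0.5 * (inverse + inverse.T)
    return UnitInformation(
        matrix=matrix, inverse=inverse, n_source=n, condition=condition, names=names
    )


def parameter_covariance(info: UnitInformation, n: int | float) -> np.ndarray:
    """var(beta_hat) = n^{-1} I^{-1} for a development sample of size n."""
    if n <= 0:
        raise ValueError("n must be positive")
    return info.inverse / n
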