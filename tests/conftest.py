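"""Shared fixtures: small hand-built cohorts and a session-scoped
synthetic breast-cancer-like cohort reused across module tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pmstability_tte import (
    Cohort,
    ColumnInfo,
    Fixture,
    gbsg_like,
    generate_fixture,
)


def make_cohort(
    time: np.ndarray | None = None,
    event: np.ndarray | None = None,
    kinds: dict[str, str] | None = None,
    **columns: np.ndarray,
) -> Cohort:
    """Build a Cohort directly from keyword arrays (kind defaults to
    continuous; override per column via ``kinds``)."""
    kinds = kinds or {}
    if columns:
        pred = pd.DataFrame({k: np.asarray(v, float) for k, v in columns.items()})
    else:  # intercept-only cohorts carry no predictor columns
        pred = pd.DataFrame(index=range(len(np.asarray(time))))
    meta = {
        k: ColumnInfo(name=k, kind=kinds.get(k, "continuous")) for k in pred.columns
    }
    return Cohort(predictors=pred, columns=meta, time=time, event=event)


@pytest.fixture(scope="session")
def breast_fixture() -> Fixture:
    """GBSG-like synthetic cohort (n=2000) with a calibrated core model
    and simulated follow-up; shared read-only across the session."""
    return generate_fixture(gbsg_like(n=2000, seed=11))


@pytest.fixture()
def simple_followup_cohort() -> Cohort:
    return make_cohort(
        time=np.array([1.0, 2.0, 3.0]),
        event=np.array([1.0, 0.0, 1.0]),
        age=np.array([40.0, 50.0, 60.0]),
    )
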