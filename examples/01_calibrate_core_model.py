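"""Calibrate an exponential core model to a target C-index and overall risk.

Builds a small synthetic cohort of predictor values, then finds the
intercept alpha and multiplier delta so that the model
ln(rate) = alpha + delta * (weighted sum of predictors) attains a C-index
of 0.70 and a mean 5-year event risk of 0.39 over the cohort.
"""

import numpy as np
import pandas as pd

from pmstability_tte import (
    CalibrationTarget,
    Cohort,
    ColumnInfo,
    calibrate,
    standardise,
)

rng = np.random.default_rng(1)
n = 2000
cohort = Cohort(
    predictors=pd.DataFrame(
        {
            "age": rng.normal(53, 10, n),
            "nodes": np.round(np.exp(rng.normal(1.0, 0.9, n))).clip(min=1),
            "grade_3": (rng.random(n) < 0.26).astype(float),
        }
    ),
    columns={
        "age": ColumnInfo("age", "continuous"),
        "nodes": ColumnInfo("nodes", "continuous"),
        "grade_3": ColumnInfo("grade_3", "dummy"),
    },
)
cohort = standardise(cohort, ["age", "nodes"])

result = calibrate(
    cohort,
    weights={"age": -1.0, "nodes": 2.0, "grade_3": 4.0},
    target=CalibrationTarget(target_c=0.70, target_risk=0.39),
    horizon=5.0,
)
m = result.model
print(f"alpha = {m.alpha:.4f}   (log baseline event rate per year)")
print(f"delta = {m.delta:.4f}   (multiplier on the relative weights)")
print(f"achieved C-index      = {result.achieved_c:.4f}")
print(f"achieved 5-year risk  = {result.achieved_risk:.4f}")
print(
    f"({result.c_evaluations} concordance evaluations, "
    f"{result.risk_evaluations} risk evaluations)"
)
# The calibrated pair defines the assumed-true model used by every
# downstream sample-size calculation; the achieved values confirm the
# iterative search converged to the requested operating characteristics.
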