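"""Post-fit uncertainty intervals from a fitted exponential regression.

Fits the exponential model by maximum likelihood to an observed (here
simulated) pilot cohort of 220 participants and derives each individual's
95% uncertainty interval for their 5-year risk from the inverse observed
information — the same interval machinery used at the design stage, now
anchored at the fitted coefficients.
"""

import numpy as np

from pmstability_tte import (
    fit_exponential_mle,
    gbsg_like,
    generate_fixture,
    postfit_intervals,
)

fx = generate_fixture(gbsg_like(n=220, seed=3))
fit = fit_exponential_mle(fx.cohort)

print(f"converged in {fit.iterations} Newton iterations, log-likelihood {fit.loglik:.2f}")
print("coefficients (log hazard-rate ratios):")
for name, coef, se in zip(fit.names, fit.coefficients, np.sqrt(np.diag(fit.covariance))):
    print(f"  {name:12s} {coef:8.3f}  (SE {se:.3f})")

records = postfit_intervals(fit, fx.cohort, t=5.0)
print(f"\nmean 95% interval width : {records['width'].mean():.3f}")
print(f"min / median / max      : {records['width'].min():.3f} / "
      f"{records['width'].median():.3f} / {records['width'].max():.3f}")
# With only 220 participants and 7 parameters the intervals are wide
# (mean width ~0.28 on the risk scale) — the post-fit counterpart of the
# design-stage message that a pilot-sized dataset is too small for stable
# individual-level risk estimates.
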