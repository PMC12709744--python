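"""Required sample size for target interval widths (Option B).

Inverts the prediction-variance decomposition: given a maximum acceptable
95% interval width of 0.20 for everyone whose true 5-year risk is at most
0.30, how many participants must the development dataset contain?
"""

from pmstability_tte import (
    SampleSizeSpec,
    cohort_required_n,
    gbsg_like,
    generate_fixture,
    unit_information,
)

fx = generate_fixture(gbsg_like(n=4000, seed=7))
info = unit_information(fx.cohort, fx.model)

spec = SampleSizeSpec.uniform_width(0.20)
records, overall = cohort_required_n(
    info, fx.cohort, fx.model, spec, subset=lambda r: r["risk_true"] <= 0.30
)

focus = records[records["risk_true"] <= 0.30]["n_required"]
print(f"individuals with true risk <= 0.30 : {len(focus)}")
print(f"per-individual required n          : median {focus.median():.0f}, "
      f"90th pct {focus.quantile(0.9):.0f}, max {focus.max():.0f}")
print(f"overall recommendation             : {overall}")
# The overall n is the ceiling of the maximum over the focus group — the
# only combining rule that guarantees the width target for every one of
# them. Individuals with rare predictor combinations dominate it.
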