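"""Misclassification probabilities, MAPE/RMSPE and grouped summaries."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from pmstability_tte import (
    SchemaError,
    ThresholdSpec,
    attach_metrics,
    mape,
    misclassification_probability,
    mu_for_risk,
    prediction_error,
    summarise_instability,
)

SPEC_20 = ThresholdSpec(threshold=0.20, horizon=5.0)


class TestMisclassification:
    def test_truth_on_threshold_gives_half(self):
        mu_star = SPEC_20.mu_star
        for var in (1e-6, 0.04, 1.0, 0.0):
            assert misclassification_probability(mu_star, var, SPEC_20) == 0.5

    def test_vanishing_variance_off_threshold_gives_zero(self):
        mu = float(mu_for_risk(0.39, 5.0))
        assert misclassification_probability(mu, 0.0, SPEC_20) == 0.0
        assert misclassification_probability(mu, 1e-10, SPEC_20) < 1e-12

    def test_worked_value(self):
        """True risk 0.39, threshold 0.20, sd(mu_hat)=0.2: the threshold is
        3.98 mu-scale SDs away, so misclassification ~ 3.5e-5."""
        mu = -2.3139
        out = misclassification_probability(mu, 0.2**2, SPEC_20)
        assert out == pytest.approx(3.5e-5, rel=0.05)

    def test_analytic_agrees_with_monte_carlo_across_grid(self):
        """The analytic form is the limit of the sampling construction:
        agreement within 3 binomial SEs at 1e5 draws."""
        draws = 100_000
        for i, (risk_true, sd) in enumerate(
            [(0.10, 0.3), (0.19, 0.2), (0.25, 0.4), (0.39, 0.5), (0.70, 0.8)]
        ):
            mu = float(mu_for_risk(risk_true, 5.0))
            analytic = misclassification_probability(mu, sd**2, SPEC_20)
            mc = misclassification_probability(
                mu, sd**2, SPEC_20, method="monte-carlo", draws=draws, seed=100 + i
            )
            se = math.sqrt(max(analytic * (1 - analytic), 1e-12) / draws)
            assert abs(mc - analytic) < 3 * se + 1e-9

    def test_nonincreasing_in_development_sample_size(self):
        """var(mu_hat) falls as 1/n, and Phi(-|gap|/s) falls with s."""
        mu = float(mu_for_risk(0.3, 5.0))
        base_var = 0.5
        values = [
            misclassification_probability(mu, base_var / n, SPEC_20)
            for n in (100, 355, 920, 5000)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_analytic_never_exceeds_half(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(-2, 1.5, 100)
        var = rng.uniform(0, 1, 100)
        out = misclassification_probability(mu, var, SPEC_20)
        assert (out <= 0.5).all()


class TestPredictionError:
    def test_zero_variance_gives_zero_error(self):
        m, r = prediction_error(-2.3139, 0.0, 5.0, draws=100, seed=0)
        assert m == 0.0 and r == 0.0

    def test_delta_method_value(self):
        """For small sd, MAPE ~ sqrt(2/pi) * |dF/dmu| * sd; at mu=-2.3139,
        t=5 the derivative is eta*t*exp(-eta*t) = 0.3015, so with sd=0.1
        MAPE ~ 0.0241."""
        m = mape(-2.3139, 0.1**2, 5.0, draws=400_000, seed=1)
        eta_t = math.exp(-2.3139) * 5.0
        predicted = math.sqrt(2 / math.pi) * eta_t * math.exp(-eta_t) * 0.1
        assert m == pytest.approx(predicted, rel=0.03)
        assert m == pytest.approx(0.024, abs=2e-3)

    def test_rmspe_dominates_mape(self):
        rng = np.random.default_rng(2)
        mu = rng.normal(-2, 1, 30)
        var = rng.uniform(0.001, 0.5, 30)
        m, r = prediction_error(mu, var, 5.0, draws=2000, seed=3)
        assert (r >= m).all()

    def test_seeded_determinism(self):
        a = mape(-2.0, 0.04, 5.0, draws=500, seed=9)
        b = mape(-2.0, 0.04, 5.0, draws=500, seed=9)
        assert a == b


class TestSummaries:
    def records(self):
        return pd.DataFrame(
            {
                "width": [0.1, 0.2, 0.3, 0.4],
                "mape": [0.01, 0.02, 0.03, 0.04],
                "rmspe": [0.02, 0.03, 0.04, 0.05],
                "misclassification": [0.0, 0.1, 0.2, 0.3],
                "group": ["a", "a", "b", "b"],
            }
        )

    def test_single_record_collapses_all_statistics(self):
        df = self.records().iloc[[0]]
        out = summarise_instability(df)
        row = out.iloc[0]
        for stat in ("width", "mape", "rmspe", "misclassification"):
            assert (
                row[f"{stat}_mean"]
                == row[f"{stat}_min"]
                == row[f"{stat}_median"]
                == row[f"{stat}_max"]
            )

    def test_order_statistics_are_ordered(self):
        out = summarise_instability(self.records(), by="group")
        for _, row in out.iterrows():
            for stat in ("width", "mape"):
                assert row[f"{stat}_min"] <= row[f"{stat}_median"] <= row[f"{stat}_max"]

    def test_group_means_pool_to_overall_mean(self):
        out = summarise_instability(self.records(), by="group").set_index("group")
        pooled = (
            out.loc[["a", "b"], "width_mean"] * out.loc[["a", "b"], "n_individuals"]
        ).sum() / out.loc[["a", "b"], "n_individuals"].sum()
        assert out.loc["all", "width_mean"] == pytest.approx(pooled, rel=1e-12)

    def test_unknown_group_column(self):
        with pytest.raises(SchemaError):
            summarise_instability(self.records(), by="nope")


def test_attach_metrics_adds_columns(breast_fixture):
    from pmstability_tte import precision_records, unit_information

    info = unit_information(breast_fixture.cohort, breast_fixture.model)
    rec = precision_records(breast_fixture.cohort, breast_fixture.model, info, 355)
    out = attach_metrics(rec.head(50), SPEC_20, draws=200, seed=4)
    assert {"mape", "rmspe", "misclassification"} <= set(out.columns)
    assert (out["misclassification"] <= 0.5).all()
    assert (out["mape"] >= 0).all()
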