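"""Prediction variance, risk-scale uncertainty intervals and required n."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmstability_tte import (
    SampleSizeSpec,
    UnitInformation,
    cohort_required_n,
    event_risk,
    precision_records,
    prediction_variance,
    required_n,
    required_variance_for_width,
    sample_uncertainty_distribution,
    uncertainty_interval,
    unit_information,
)


def make_info(matrix: np.ndarray) -> UnitInformation:
    matrix = np.asarray(matrix, float)
    return UnitInformation(
        matrix=matrix,
        inverse=np.linalg.inv(matrix),
        n_source=0,
        condition=float(np.linalg.cond(matrix)),
        names=tuple(f"c{i}" for i in range(matrix.shape[0])),
    )


def random_pd_info(seed: int, p: int) -> UnitInformation:
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(p, p))
    return make_info(a @ a.T + p * np.eye(p))


class TestPredictionVariance:
    def test_intercept_only(self):
        info = make_info([[1.0]])
        assert prediction_variance(info, np.array([1.0]), 355) == pytest.approx(
            1 / 355, rel=1e-15
        )

    def test_exact_inverse_n_scaling(self):
        info = random_pd_info(0, 4)
        x = np.array([1.0, 0.3, -1.2, 2.0])
        v355 = prediction_variance(info, x, 355)
        v920 = prediction_variance(info, x, 920)
        assert v920 == pytest.approx(v355 * 355 / 920, rel=1e-12)

    def test_matches_triple_loop_quadratic_form(self):
        info = random_pd_info(1, 5)
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=5)
            brute = sum(
                x[j] * info.inverse[j, k] * x[k] for j in range(5) for k in range(5)
            )
            assert prediction_variance(info, x, 123) == pytest.approx(
                brute / 123, rel=1e-12
            )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="entries"):
            prediction_variance(make_info([[1.0]]), np.array([1.0, 2.0]), 10)


class TestUncertaintyInterval:
    def test_zero_variance_degenerates_to_truth(self):
        lo, hi = uncertainty_interval(-2.3139, 0.0, 5.0)
        truth = event_risk(-2.3139, 5.0)
        assert lo == hi == pytest.approx(truth, abs=1e-15)

    def test_worked_interval_at_population_risk(self):
        """mu = -2.3139, var = 0.01, t = 5: the 95% mu-interval is
        (-2.5099, -2.1179) mapping to risks about (0.334, 0.452)."""
        lo, hi = uncertainty_interval(-2.3139, 0.01, 5.0, 0.95)
        assert lo == pytest.approx(0.334, abs=5e-4)
        assert hi == pytest.approx(0.452, abs=5e-4)
        assert hi - lo == pytest.approx(0.118, abs=1e-3)

    @given(mu=st.floats(-6, -0.5), var=st.floats(1e-6, 2.0))  # away from risk saturation at 1
    @settings(max_examples=80, deadline=None)
    def test_interval_contains_truth_and_width_grows(self, mu, var):
        lo, hi = uncertainty_interval(mu, var, 5.0)
        truth = event_risk(mu, 5.0)
        assert lo <= truth <= hi
        lo4, hi4 = uncertainty_interval(mu, 4 * var, 5.0)
        assert hi4 - lo4 > hi - lo
        assert 0.0 <= lo and hi <= 1.0

    def test_mu_scale_half_width_scales_as_inverse_sqrt_n(self):
        info = random_pd_info(3, 3)
        x = np.array([1.0, 0.5, -0.5])
        widths = {}
        for n in (100, 400, 1600):
            v = prediction_variance(info, x, n)
            widths[n] = 1.96 * math.sqrt(v)
        assert widths[400] == pytest.approx(widths[100] / 2, rel=1e-12)
        assert widths[1600] == pytest.approx(widths[100] / 4, rel=1e-12)


class TestUncertaintyDistribution:
    def test_zero_variance_collapses(self):
        draws = sample_uncertainty_distribution(-2.0, 0.0, 5.0, 50, seed=0)
        assert np.ptp(draws) == 0.0

    def test_seeded_determinism(self):
        a = sample_uncertainty_distribution(-2.0, 0.02, 5.0, 100, seed=7)
        b = sample_uncertainty_distribution(-2.0, 0.02, 5.0, 100, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_percentiles_agree_with_interval_bounds(self):
        draws = sample_uncertainty_distribution(-2.3139, 0.01, 5.0, 100_000, seed=1)
        lo, hi = uncertainty_interval(-2.3139, 0.01, 5.0, 0.95)
        q_lo, q_hi = np.percentile(draws, [2.5, 97.5])
        assert q_lo == pytest.approx(lo, abs=2e-3)
        assert q_hi == pytest.approx(hi, abs=2e-3)


class TestRequiredVarianceAndN:
    def test_width_round_trip(self):
        for band, width in ((0.05, 0.08), (0.2, 0.2), (0.39, 0.118)):
            var = required_variance_for_width(band, width, t=5.0)
            mu = math.log(-math.log(1 - band) / 5.0)
            lo, hi = uncertainty_interval(mu, var, 5.0)
            assert hi - lo == pytest.approx(width, abs=1e-8)

    def test_inverse_of_worked_interval(self):
        # width 0.118 at risk 0.39 corresponds to var(mu_hat) near 0.01
        var = required_variance_for_width(0.39, 0.118, t=5.0)
        assert var == pytest.approx(0.01, abs=1e-4)

    def test_small_width_needs_small_variance(self):
        v1 = required_variance_for_width(0.2, 0.01, t=5.0)
        v2 = required_variance_for_width(0.2, 0.001, t=5.0)
        assert v2 < v1 < 1e-2
        assert v2 < 1e-5

    def test_unattainable_width_rejected(self):
        with pytest.raises(ValueError):
            required_variance_for_width(0.2, 1.0, t=5.0)

    def test_required_n_round_trip_exact(self):
        info = random_pd_info(4, 3)
        x = np.array([1.0, -0.7, 0.4])
        for v in (1e-3, 0.01, 0.2):
            n = required_n(info, x, v)
            assert prediction_variance(info, x, n.raw) == pytest.approx(v, rel=1e-12)
            assert n.rounded == math.ceil(n.raw)

    def test_intercept_only_values(self):
        info = make_info([[1.0]])
        n = required_n(info, np.array([1.0]), 0.01)
        assert n.raw == pytest.approx(100.0, rel=1e-12)
        assert n.rounded == 100


class TestCohortRequiredN:
    def test_homogeneous_cohort_gives_identical_n(self, breast_fixture):
        # replicate one individual's predictor row 40 times
        uniform = breast_fixture.cohort.subset(np.arange(2000) < 40)
        uniform.predictors.iloc[:, :] = np.tile(
            breast_fixture.cohort.predictors.to_numpy()[0], (40, 1)
        )
        info = unit_information(breast_fixture.cohort, breast_fixture.model)
        records, overall = cohort_required_n(
            info, uniform, breast_fixture.model, SampleSizeSpec.uniform_width(0.2)
        )
        assert records["n_required"].nunique() == 1
        assert overall == math.ceil(records["n_required"].iloc[0])

    def test_tightening_a_band_never_reduces_overall_n(self, breast_fixture):
        info = unit_information(breast_fixture.cohort, breast_fixture.model)
        loose = SampleSizeSpec.uniform_width(0.25)
        tight = SampleSizeSpec.uniform_width(0.15)
        _, n_loose = cohort_required_n(
            info, breast_fixture.cohort, breast_fixture.model, loose
        )
        _, n_tight = cohort_required_n(
            info, breast_fixture.cohort, breast_fixture.model, tight
        )
        assert n_tight >= n_loose

    def test_n_scales_with_inverse_variance_target(self, breast_fixture):
        """Doubling every width target rescales each individual's n by the
        ratio of the band variance targets (n proportional to 1/var)."""
        info = unit_information(breast_fixture.cohort, breast_fixture.model)
        spec1 = SampleSizeSpec.uniform_width(0.1)
        spec2 = SampleSizeSpec.uniform_width(0.2)
        r1, _ = cohort_required_n(info, breast_fixture.cohort, breast_fixture.model, spec1)
        r2, _ = cohort_required_n(info, breast_fixture.cohort, breast_fixture.model, spec2)
        ratio = r1["n_required"] / r2["n_required"]
        expected = r2["var_target"] / r1["var_target"]
        np.testing.assert_allclose(ratio, expected, rtol=1e-10)

    def test_band_assignment_prefers_lower_on_ties(self):
        spec = SampleSizeSpec(bands=(0.1, 0.2), target_widths=(0.2, 0.2))
        idx = spec.assign_bands(np.array([0.15, 0.10, 0.149, 0.151]))
        np.testing.assert_array_equal(idx, [0, 0, 0, 1])

    def test_empty_subset_rejected(self, breast_fixture):
        from pmstability_tte import StateError

        info = unit_information(breast_fixture.cohort, breast_fixture.model)
        with pytest.raises(StateError):
            cohort_required_n(
                info,
                breast_fixture.cohort,
                breast_fixture.model,
                SampleSizeSpec.uniform_width(0.2),
                subset=lambda r: r["risk_true"] < -1,
            )


def test_precision_records_shape_and_invariants(breast_fixture):
    info = unit_information(breast_fixture.cohort, breast_fixture.model)
    rec = precision_records(breast_fixture.cohort, breast_fixture.model, info, 355)
    assert len(rec) == breast_fixture.cohort.n
    assert ((rec["lower"] <= rec["risk_true"]) & (rec["risk_true"] <= rec["upper"])).all()
    assert (rec["width"] >= 0).all() and (rec["width"] < 1).all()
    assert (rec["var_mu"] > 0).all()
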