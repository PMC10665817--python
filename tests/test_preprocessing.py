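"""Correction-chain numerics: smoothing, airPLS, standardization, the
non-negative Lasso reference fit, and the composed zdF/F computation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.pipeline import Pipeline

import fiberflow as ff
from fiberflow.datatypes import AlignmentError, DataError
from fiberflow.preprocessing import (AirPLS, MovingAverageSmoother,
                                     PreprocessParams, ReferenceRegressor,
                                     airpls_baseline, fit_reference, smooth,
                                     standardize, whittaker_smooth)


def _trace(values, rate=10.0):
    values = np.asarray(values, dtype=float)
    return ff.PhotometryTrace(np.arange(len(values)) / rate, values,
                              nominal_rate_hz=rate)


class TestSmooth:
    def test_constant_preserved(self):
        tr = _trace(np.full(100, 3.5))
        out = smooth(tr, PreprocessParams(smooth_window_s=1.0))
        np.testing.assert_allclose(out.value, 3.5, atol=1e-12)
        np.testing.assert_array_equal(out.timestamp_s, tr.timestamp_s)

    def test_impulse_through_width5_average(self):
        y = np.zeros(51)
        y[25] = 1.0
        out = smooth(_trace(y), PreprocessParams(smooth_window_s=0.5))
        np.testing.assert_allclose(out.value[23:28], 0.2, atol=1e-12)
        assert out.value[:23].max() == 0.0 and out.value[28:].max() == 0.0

    def test_4hz_sine_attenuated(self):
        # moving-average frequency response at 4 Hz / 10 Hz sampling,
        # 0.5-s (5-sample) window: |sin(pi f N/fs) / (N sin(pi f/fs))|
        t = np.arange(500) / 10.0
        y = np.sin(2 * np.pi * 4.0 * t)
        out = smooth(_trace(y), PreprocessParams(smooth_window_s=0.5))
        gain_oracle = abs(np.sin(np.pi * 4 * 5 / 10)
                          / (5 * np.sin(np.pi * 4 / 10)))
        amp = out.value[50:-50].max()
        assert amp < 0.25
        assert amp == pytest.approx(max(gain_oracle, 0.0), abs=0.02)

    def test_lowpass_alternative_zero_phase(self):
        t = np.arange(400) / 10.0
        slow = np.sin(2 * np.pi * 0.2 * t)
        out = smooth(_trace(slow),
                     PreprocessParams(smooth_window_s=None,
                                      lowpass_cutoff_hz=2.0))
        lagstep = np.argmax(np.correlate(out.value[50:-50], slow[50:-50],
                                         "full")) - (len(slow[50:-50]) - 1)
        assert lagstep == 0

    def test_too_short_trace_rejected(self):
        with pytest.raises(DataError):
            smooth(_trace(np.zeros(5)), PreprocessParams(smooth_window_s=1.0))


class TestAirPLS:
    def test_constant_input_is_its_own_baseline(self):
        y = np.full(50, 2.0)
        np.testing.assert_allclose(airpls_baseline(y, lam=1e4), y, atol=1e-6)

    def test_line_matches_uniform_whittaker_oracle(self):
        y = np.linspace(0.0, 5.0, 200)
        base = airpls_baseline(y, lam=1e4)
        oracle = whittaker_smooth(y, np.ones_like(y), 1e4)
        rng_y = y.max() - y.min()
        assert np.max(np.abs(base - y)) < 1e-3 * rng_y
        assert np.max(np.abs(base - oracle)) < 1e-3 * rng_y

    def test_peak_free_smooth_input_oracle_equivalence(self):
        t = np.linspace(0, 10, 400)
        y = 3.0 + 0.5 * np.sin(2 * np.pi * 0.05 * t)
        base = airpls_baseline(y, lam=1e4)
        oracle = whittaker_smooth(y, np.ones_like(y), 1e4)
        assert np.max(np.abs(base - oracle)) < 1e-3 * (y.max() - y.min())

    def test_baseline_sinks_under_positive_peak(self):
        n = 400
        x = np.arange(n, dtype=float)
        line = 1.0 + 0.01 * x  # range ~4
        peak_height = 10.0 * (line.max() - line.min())
        y = line + peak_height * np.exp(-0.5 * ((x - 200) / 8.0) ** 2)
        base, info = airpls_baseline(y, lam=1e4, max_iter=50,
                                     return_info=True)
        assert abs(base[200] - line[200]) < 0.05 * peak_height
        hist = info["neg_residual_history"]
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_baseline_never_exceeds_global_max(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=300).cumsum() + 10 * np.exp(
            -0.5 * ((np.arange(300) - 150) / 10.0) ** 2)
        base = airpls_baseline(y, lam=1e6)
        assert base.max() <= y.max() + 1e-9

    def test_nonfinite_rejected(self):
        y = np.ones(10)
        y[3] = np.nan
        with pytest.raises(DataError):
            airpls_baseline(y)


class TestStandardize:
    def test_basic_exact(self):
        z, flag = standardize([1.0, 2.0, 3.0])
        assert not flag
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1.0) < 1e-12

    def test_constant_degenerate(self):
        z, flag = standardize(np.full(20, 7.0))
        assert flag
        np.testing.assert_array_equal(z, 0.0)

    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_affine_invariance(self, a, b):
        y = np.array([0.3, -1.2, 2.4, 0.0, 5.5])
        z1, _ = standardize(y)
        z2, _ = standardize(a * y + b)
        np.testing.assert_allclose(z1, z2, atol=1e-9)


class TestFitReference:
    def test_identical_inputs_slope_one(self):
        rng = np.random.default_rng(1)
        z, _ = standardize(rng.normal(size=500))
        fit = fit_reference(z, z, l1_alpha=0.0)
        assert abs(fit.slope_a - 1.0) < 1e-6
        assert abs(fit.intercept_b) < 1e-6

    def test_anticorrelated_clamped_to_zero(self):
        rng = np.random.default_rng(2)
        z, _ = standardize(rng.normal(size=500))
        fit = fit_reference(z, -z, l1_alpha=1e-3)
        assert fit.slope_a == 0.0

    def test_recovers_planted_slope_against_soft_threshold_oracle(self):
        rng = np.random.default_rng(3)
        x, _ = standardize(rng.normal(size=2000))
        y = 0.7 * x + rng.normal(scale=0.3, size=2000)
        alpha = 1e-3
        fit = fit_reference(x, y, l1_alpha=alpha)
        # closed-form 1-D lasso on standardized x: soft-threshold the
        # empirical covariance by alpha, divide by var, clamp at zero
        yc = y - y.mean()
        cov = float(x @ yc) / len(x)
        var = float(x @ x) / len(x)
        oracle = max((cov - alpha), 0.0) / var
        assert abs(fit.slope_a - 0.7) < 0.05
        assert fit.slope_a == pytest.approx(oracle, abs=1e-3)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            fit_reference(np.zeros(5), np.zeros(6))

    def test_fitted_reference_is_affine_in_reference(self):
        rng = np.random.default_rng(4)
        x, _ = standardize(rng.normal(size=100))
        y, _ = standardize(rng.normal(size=100))
        fit = fit_reference(x, y, l1_alpha=1e-4)
        np.testing.assert_allclose(fit.fitted_reference,
                                   fit.slope_a * x + fit.intercept_b,
                                   atol=1e-12)


class TestComputeZdff:
    def test_recovers_clean_transients(self, default_session, default_zdff):
        _, _, _, _, truth = default_session
        clean = truth.clean_transient_trace["470"]
        r = np.corrcoef(default_zdff.value, clean)[0, 1]
        assert r >= 0.8

    def test_variance_reduction_without_transients(self):
        cfg = ff.SynthConfig(duration_s=300.0, transient_rate_hz=0.0,
                             artifact_rate_hz=0.5, artifact_amp=5.0, seed=4)
        rec, *_ = ff.generate_session(cfg)
        traces = ff.deinterleave(rec)
        z = ff.compute_zdff(traces["470"], traces["415"])
        z_unc, _ = standardize(traces["470"].value)
        assert np.std(z.value) < 0.5 * np.std(z_unc)

    def test_self_subtraction_is_zero(self, default_traces):
        ref = default_traces["415"]
        z = ff.compute_zdff(ref, ref, PreprocessParams(l1_alpha=0.0))
        assert np.max(np.abs(z.value)) < 1e-6

    def test_mean_free_when_unregularized(self, default_traces):
        z = ff.compute_zdff(default_traces["470"], default_traces["415"],
                            PreprocessParams(l1_alpha=0.0))
        assert abs(z.value.mean()) < 1e-6

    def test_invariant_to_camera_gain_and_offset(self, default_session):
        _, rec, *_ = default_session
        traces = ff.deinterleave(rec)
        sig, ref = traces["470"], traces["415"]
        z1 = ff.compute_zdff(sig, ref)
        z2 = ff.compute_zdff(sig.with_values(3.7 * sig.value + 12.0),
                             ref.with_values(0.5 * ref.value + 40.0))
        # the airPLS stopping rule is relative to total absolute signal, so
        # an offset can change the iteration count by one; agreement is
        # tight but not bitwise
        np.testing.assert_allclose(z1.value, z2.value, atol=1e-4)

    def test_better_artifact_sharing_never_hurts(self):
        # residual artifact correlation with a high-gain reference must not
        # exceed the one with a half-gain reference (same noise draws)
        rng = np.random.default_rng(5)
        n = 3000
        t = np.arange(n) / 10.0
        artifact = np.zeros(n)
        for idx in rng.choice(n - 200, 40):
            artifact[idx:idx + 60] += rng.normal() * np.exp(-np.arange(60) / 15.0)
        transients = np.zeros(n)
        for idx in rng.choice(n - 200, 80):
            transients[idx:idx + 40] += np.exp(-np.arange(40) / 10.0)
        noise_s = rng.normal(0, 0.3, n)
        noise_r = rng.normal(0, 0.3, n)
        sig = ff.PhotometryTrace(t, 50 + transients + artifact + noise_s,
                                 nominal_rate_hz=10.0)
        resid = []
        for gain in (0.5, 1.0):
            ref = ff.PhotometryTrace(t, 40 + gain * artifact + noise_r,
                                     nominal_rate_hz=10.0)
            z = ff.compute_zdff(sig, ref)
            resid.append(abs(np.corrcoef(z.value, artifact)[0, 1]))
        assert resid[1] <= resid[0] + 0.02

    def test_disjoint_time_support_rejected(self):
        a = ff.PhotometryTrace(np.arange(100) / 10.0, np.random.default_rng(0).normal(size=100))
        b = ff.PhotometryTrace(100.0 + np.arange(100) / 10.0,
                               np.random.default_rng(1).normal(size=100))
        with pytest.raises(AlignmentError):
            ff.compute_zdff(a, b)


class TestSklearnFacade:
    def test_airpls_transformer_matches_function(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=200).cumsum()
        est = AirPLS(lam=1e5).fit(y)
        np.testing.assert_allclose(est.baseline_[:, 0],
                                   airpls_baseline(y, lam=1e5), atol=1e-9)
        np.testing.assert_allclose(est.transform(y)[:, 0],
                                   y - est.baseline_[:, 0], atol=1e-12)

    def test_clone_roundtrip(self):
        for est in (AirPLS(lam=2.0, max_iter=7),
                    MovingAverageSmoother(window_s=0.5, rate_hz=20.0),
                    ReferenceRegressor(alpha=0.01),
                    ff.ZdFF(airpls_lambda=5.0)):
            assert clone(est).get_params() == est.get_params()

    def test_pipeline_composition(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 2)).cumsum(axis=0)
        pipe = Pipeline([("smooth", MovingAverageSmoother(0.5, 10.0)),
                         ("detrend", AirPLS(lam=1e6))])
        out = pipe.fit_transform(X)
        assert out.shape == X.shape

    def test_reference_regressor_predicts_affine(self):
        rng = np.random.default_rng(8)
        x, _ = standardize(rng.normal(size=500))
        y = 0.4 * x + rng.normal(0, 0.1, 500)
        est = ReferenceRegressor(alpha=1e-4).fit(x, y)
        np.testing.assert_allclose(est.predict(x),
                                   est.coef_[0] * x + est.intercept_,
                                   atol=1e-12)

    def test_zdff_estimator_exposes_fit_attributes(self, default_traces):
        est = ff.ZdFF().fit(default_traces["470"], default_traces["415"])
        assert est.slope_a_ >= 0
        assert est.zdff_.value.shape == default_traces["470"].value.shape
        np.testing.assert_array_equal(est.transform(), est.zdff_.value)
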