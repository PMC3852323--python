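import dataclasses
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import respcal as rc
from respcal.calibration import (
    ExtraTerms,
    RankDeficiencyWarning,
    _fit_at_delay,
)
from respcal.errors import InsufficientDataError, SamplingRateError

from conftest import make_recording


class TestWindowToTaps:
    @pytest.mark.parametrize(
        "window_s,fs,expected", [(0.3, 50, 16), (0.15, 50, 8), (0.02, 50, 2)]
    )
    def test_inclusive_endpoint_convention(self, window_s, fs, expected):
        assert rc.window_to_taps(window_s, fs) == expected

    @pytest.mark.parametrize("window_s,fs", [(0.0, 50), (-1, 50), (0.3, 0)])
    def test_non_positive_inputs_rejected(self, window_s, fs):
        with pytest.raises(ValueError):
            rc.window_to_taps(window_s, fs)


def brute_force_design(x1, x2, N):
    """Independent loop oracle for the lagged design-matrix layout."""
    n = len(x1) - N + 1
    X = np.empty((n, 2 * N))
    for i in range(n):
        for j in range(N):
            X[i, j] = x1[i + j]
            X[i, N + j] = x2[i + j]
    return X


class TestDesignMatrix:
    def test_worked_example(self):
        dm = rc.build_design_matrix([1, 2, 3, 4], [10, 20, 30, 40], N=2)
        np.testing.assert_array_equal(
            dm.X, [[1, 2, 10, 20], [2, 3, 20, 30], [3, 4, 30, 40]]
        )
        assert dm.n == 3

    def test_single_tap_is_column_stack(self):
        x1, x2 = np.arange(5.0), np.arange(5.0) * 2
        dm = rc.build_design_matrix(x1, x2, N=1)
        np.testing.assert_array_equal(dm.X, np.column_stack([x1, x2]))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        length=st.integers(10, 60),
        N=st.integers(1, 9),
        seed=st.integers(0, 10_000),
    )
    def test_matches_brute_force_oracle(self, length, N, seed):
        rng = np.random.default_rng(seed)
        x1 = rng.standard_normal(length)
        x2 = rng.standard_normal(length)
        dm = rc.build_design_matrix(x1, x2, N)
        np.testing.assert_array_equal(dm.X, brute_force_design(x1, x2, N))
        assert dm.n == length - N + 1

    def test_too_short_signal_rejected(self):
        with pytest.raises(InsufficientDataError):
            rc.build_design_matrix([1, 2], [1, 2], N=3)

    def test_extra_columns(self):
        x1 = np.array([1.0, 2.0, 3.0])
        x2 = np.array([4.0, 5.0, 6.0])
        dm = rc.build_design_matrix(
            x1, x2, N=2, extra=ExtraTerms(intercept=True, squares=True, cross=True)
        )
        assert dm.X.shape == (2, 8)
        np.testing.assert_array_equal(dm.X[:, 4], [1, 1])  # intercept
        np.testing.assert_array_equal(dm.X[:, 5], [1, 4])  # x1^2 at window start
        np.testing.assert_array_equal(dm.X[:, 6], [16, 25])  # x2^2
        np.testing.assert_array_equal(dm.X[:, 7], [4, 10])  # x1*x2
        assert dm.extra_terms == ["intercept", "x1_sq", "x2_sq", "x1_x2"]


class TestLeastSquares:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.standard_normal((2, 100))
        dm = rc.build_design_matrix(x1, x2, N=1)
        beta = rc.fit_least_squares(dm, 2 * x1 + 3 * x2)
        np.testing.assert_allclose(beta, [2, 3], atol=1e-9)

    def test_orthogonal_target_gives_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        y -= X @ np.linalg.solve(X.T @ X, X.T @ y)  # orthogonalize
        beta = rc.fit_least_squares(X, y)
        np.testing.assert_allclose(beta, 0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((30, 6))
        y = rng.standard_normal(30)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(rc.fit_least_squares(X, y), oracle, atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rc.fit_least_squares(np.ones((5, 2)), np.ones(4))

    def test_rank_deficiency_warns_minimum_norm(self):
        x = np.arange(20.0)
        X = np.column_stack([x, 2 * x])  # collinear
        with pytest.warns(RankDeficiencyWarning):
            beta = rc.fit_least_squares(X, 5 * x)
        np.testing.assert_allclose(X @ beta, 5 * x, atol=1e-9)


class TestPredict:
    def _model(self, beta1, beta2, N, D=0, fs=50.0):
        return rc.CalibrationModel(beta1=beta1, beta2=beta2, N=N, D=D, fs=fs)

    def test_identity_tap_returns_input(self):
        m = self._model([1, 0, 0], [0, 0, 0], N=3)
        x1 = np.random.default_rng(0).standard_normal(40)
        res = rc.predict(m, x1, np.zeros(40))
        np.testing.assert_allclose(res.y_hat.samples, x1[:38], atol=1e-12)

    def test_zero_taps_give_zero(self):
        m = self._model(np.zeros(4), np.zeros(4), N=4)
        res = rc.predict(m, np.ones(30), np.ones(30))
        np.testing.assert_array_equal(res.y_hat.samples, np.zeros(27))

    def test_sampling_rate_mismatch_rejected(self):
        m = self._model([1], [1], N=1, fs=50)
        with pytest.raises(SamplingRateError):
            rc.predict(m, np.ones(10), np.ones(10), fs=100)

    def test_known_fir_mixture_is_reconstructed(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.standard_normal((2, 500))
        b1 = np.array([0.5, -0.2, 0.1])
        b2 = np.array([0.3, 0.3, -0.4])
        dm = rc.build_design_matrix(x1, x2, N=3)
        y = dm.X @ np.concatenate([b1, b2])
        rec = make_recording(x1, x2, np.concatenate([y, np.zeros(2)]))
        model = rc.fit_proposed(rec, N=3, delay_search_s=0, center=False)
        res = rc.predict(model, x1, x2)
        assert rc.r_squared(y, res.y_hat.samples) > 0.999


class TestDelayEstimation:
    def _signals(self, seed=0, n=2000):
        rng = np.random.default_rng(seed)
        x1, x2 = rng.standard_normal((2, n))
        return x1, x2

    def test_zero_shift_recovered(self):
        x1, x2 = self._signals()
        y = x1.copy()
        assert rc.estimate_delay(x1, x2, y, N=4, search=20) == 0

    def test_injected_shift_recovered(self):
        x1, x2 = self._signals(1)
        b1 = np.array([0.4, 0.3, 0.2, 0.1])
        b2 = np.array([0.1, -0.2, 0.3, 0.2])
        dm = rc.build_design_matrix(x1, x2, N=4)
        y0 = dm.X @ np.concatenate([b1, b2])
        shift = 5
        y = np.zeros_like(x1)
        idx = np.clip(np.arange(len(y)) - shift, 0, len(y0) - 1)
        y = y0[idx]
        assert rc.estimate_delay(x1, x2, y, N=4, search=10, center=False) == shift

    def test_scores_match_exhaustive_refit_oracle(self):
        x1, x2 = self._signals(2, n=600)
        rng = np.random.default_rng(5)
        y = 0.3 * x1 + 0.2 * x2 + 0.05 * rng.standard_normal(600)
        search = 6
        N = 3
        D, scores = rc.estimate_delay(
            x1, x2, y, N=N, search=search, center=False, full_output=True
        )
        # oracle: independent full least-squares refit at every shift on the
        # same shared row window
        dm = rc.build_design_matrix(x1, x2, N)
        lo, hi = search, min(dm.n - 1, len(y) - 1 - search)
        Xs = dm.X[lo : hi + 1]
        for d in range(-search, search + 1):
            yd = y[lo + d : hi + d + 1]
            beta, *_ = np.linalg.lstsq(Xs, yd, rcond=None)
            rms = np.sqrt(np.mean((yd - Xs @ beta) ** 2))
            assert scores[d] == pytest.approx(rms, abs=1e-10)
        assert D == min(scores, key=lambda d: (scores[d], abs(d), d))

    def test_insufficient_rows_rejected(self):
        x1, x2 = self._signals(3, n=50)
        with pytest.raises(InsufficientDataError):
            rc.estimate_delay(x1, x2, x1, N=4, search=20)


class TestFitProposed:
    def test_window_gives_sixteen_taps(self, step8_recording):
        model = rc.fit_proposed(step8_recording, window_s=0.3)
        assert model.N == 16

    def test_noiseless_tap_recovery(self):
        rng = np.random.default_rng(11)
        x1, x2 = rng.standard_normal((2, 1500))
        N = 6
        b1, b2 = rng.standard_normal((2, N))
        dm = rc.build_design_matrix(x1, x2, N)
        y0 = dm.X @ np.concatenate([b1, b2])
        y = y0[np.clip(np.arange(1500), 0, len(y0) - 1)]
        rec = make_recording(x1, x2, y)
        model = rc.fit_proposed(rec, N=N, delay_search_s=0.2, center=False)
        assert model.D == 0
        np.testing.assert_allclose(model.beta1, b1, atol=1e-6)
        np.testing.assert_allclose(model.beta2, b2, atol=1e-6)
        assert model.training_residual_rms < 1e-9

    def test_intercept_is_inert_after_centering(self, step8_recording):
        plain = rc.fit_proposed(step8_recording, window_s=0.15)
        with_ic = rc.fit_proposed(
            step8_recording, window_s=0.15, extra=ExtraTerms(intercept=True)
        )
        p1 = rc.evaluate(plain, step8_recording).y_hat.samples
        p2 = rc.evaluate(with_ic, step8_recording).y_hat.samples
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_serialization_round_trip(self, tmp_path, step8_recording):
        model = rc.fit_proposed(step8_recording, window_s=0.15)
        path = tmp_path / "model.json"
        model.save(path)
        back = rc.CalibrationModel.load(path)
        assert back.N == model.N and back.D == model.D
        np.testing.assert_array_equal(back.beta1, model.beta1)
        rec = step8_recording
        np.testing.assert_allclose(
            rc.evaluate(back, rec).y_hat.samples,
            rc.evaluate(model, rec).y_hat.samples,
        )
        assert json.loads(path.read_text())["schema_version"] == 1


class TestModelProperties:
    def test_reduces_to_standard_method(self, free_recording):
        prop = rc.fit_proposed(free_recording, N=1, delay_search_s=0)
        std = rc.fit_standard(free_recording)
        p1 = rc.evaluate(prop, free_recording).y_hat.samples
        p2 = rc.predict_standard(std, free_recording).y_hat.samples
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_training_r2_non_decreasing_in_taps(self, step8_recording):
        rec = step8_recording
        Ns = [1, 2, 4, 8, 16]
        n_max = max(Ns)
        r2s = []
        for N in Ns:
            # trim so every N sees the identical target rows (nested models)
            cut = n_max - N
            trimmed = make_recording(
                rec.ribcage.samples[: len(rec.ribcage) - cut],
                rec.abdomen.samples[: len(rec.abdomen) - cut],
                rec.spirometer.samples,
                fs=rec.fs,
            )
            m = rc.fit_proposed(trimmed, N=N, delay_search_s=0)
            pred = rc.predict(
                m,
                trimmed.ribcage,
                trimmed.abdomen,
                y_ref=rec.spirometer.samples,
            )
            r2s.append(rc.r_squared(pred.y_ref.samples, pred.y_hat.samples))
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_scale_equivariance(self, step8_recording):
        rec = step8_recording
        c = 3.7
        scaled = make_recording(
            c * rec.ribcage.samples,
            rec.abdomen.samples,
            rec.spirometer.samples,
            fs=rec.fs,
        )
        m0 = rc.fit_proposed(rec, window_s=0.15)
        m1 = rc.fit_proposed(scaled, window_s=0.15)
        assert m1.D == m0.D
        np.testing.assert_allclose(m1.beta1, m0.beta1 / c, rtol=1e-8)
        p0 = rc.evaluate(m0, rec).y_hat.samples
        p1 = rc.evaluate(m1, scaled).y_hat.samples
        np.testing.assert_allclose(p0, p1, atol=1e-9)

    def test_residual_orthogonal_to_design(self, step8_recording):
        rec = step8_recording
        model = rc.fit_proposed(rec, window_s=0.3)
        x1 = rec.ribcage.samples
        x2 = rec.abdomen.samples
        y = rec.spirometer.samples
        beta, col_mu, y_mu, _ = _fit_at_delay(
            x1, x2, y, model.N, model.D, model.extra
        )
        dm = rc.build_design_matrix(x1, x2, model.N)
        lo = max(0, -model.D)
        hi = min(dm.n - 1, y.size - 1 - model.D)
        Xv = dm.X[lo : hi + 1] - col_mu
        resid = (y[lo + model.D : hi + model.D + 1] - y_mu) - Xv @ beta
        stat = np.abs(Xv.T @ resid).max() / (
            Xv.shape[0] * np.abs(Xv).max() * np.abs(y).max()
        )
        assert stat <= 1e-8

    @pytest.mark.parametrize("shift", [-30, -5, 0, 5, 30])
    def test_known_system_recovery(self, shift):
        sc = rc.SyntheticScenario(
            duration_s=60, fs=50, noise_sd=0.01, drift=0.0, seed=21
        )
        rng = np.random.default_rng(shift + 77)
        N = 8
        b1 = rng.standard_normal(N) * 0.6 ** np.arange(N)
        b2 = rng.standard_normal(N) * 0.6 ** np.arange(N)
        rec, _ = rc.known_fir_recording(sc, b1, b2, shift)
        model = rc.fit_proposed(rec, N=N, delay_search_s=1.0, center=False)
        assert model.D == shift
        pred = rc.evaluate(model, rec)
        assert rc.r_squared(pred.y_ref.samples, pred.y_hat.samples) >= 1 - 1e-9
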