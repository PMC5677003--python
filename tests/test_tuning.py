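import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from serialdep import tuning as t
from conftest import make_xy


class TestDoGCurve:
    def test_zero_at_origin_and_for_zero_amplitude(self):
        p = t.DoGParams(a=3.0, w=0.02)
        assert t.dog_curve(0.0, p) == 0.0
        assert np.all(t.dog_curve(np.linspace(-180, 180, 50), t.DoGParams(0.0, 0.02)) == 0)

    def test_peak_height_equals_amplitude(self):
        # analytic maximum at x = 1/(w*sqrt(2)); dense-grid oracle agrees
        a, w = 3.0, 0.02
        p = t.DoGParams(a, w)
        x_peak = 1.0 / (w * np.sqrt(2.0))
        assert x_peak == pytest.approx(35.355, abs=0.01)
        assert t.dog_curve(x_peak, p) == pytest.approx(a, abs=1e-12)
        grid = np.linspace(-180, 180, 100_001)
        assert t.dog_curve(grid, p).max() == pytest.approx(a, abs=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(-10, 10),
        w=st.floats(0.002, 0.2),
        x=st.floats(-180, 180),
    )
    def test_odd_function(self, a, w, x):
        p = t.DoGParams(a, w)
        assert t.dog_curve(-x, p) == pytest.approx(-t.dog_curve(x, p), abs=1e-9)


class TestCliffordCurve:
    def test_zero_at_origin(self):
        assert t.clifford_curve(0.0, t.CliffordParams(0.9, 0.1)) == 0.0

    def test_identity_parameters_give_flat_curve(self):
        x = np.linspace(-180, 180, 361)
        y = t.clifford_curve(x, t.CliffordParams(1.0, 0.0, 1))
        assert np.max(np.abs(y)) < 1e-9

    def test_matches_root_find_on_continuous_branch(self):
        # independent oracle: solve the implicit equation for y, picking the
        # root continuous with y(0) = 0
        s, c, x = 1.0, 0.2, 45.0
        xr = np.deg2rad(x)
        rhs = np.sin(xr) / np.hypot(s * np.cos(xr) - c, np.sin(xr))
        yg = np.deg2rad(np.linspace(-90, 90, 20001))
        h = np.sin(yg + xr) - rhs
        roots = []
        for i in np.nonzero(np.sign(h[1:]) != np.sign(h[:-1]))[0]:
            roots.append(optimize.brentq(
                lambda y: np.sin(y + xr) - rhs, yg[i], yg[i + 1], xtol=1e-14))
        y_oracle = np.rad2deg(min(roots, key=abs))
        y_impl = t.clifford_curve(x, t.CliffordParams(s, c, 1))
        assert y_impl == pytest.approx(y_oracle, abs=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(
        s=st.floats(0.6, 1.4),
        c=st.floats(-0.35, 0.35),
        x=st.floats(0, 180),
    )
    def test_odd_function(self, s, c, x):
        p = t.CliffordParams(s, c, 1)
        assert t.clifford_curve(-x, p) == pytest.approx(-t.clifford_curve(x, p), abs=1e-9)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            t.CliffordParams(s_scale=1.0, c_center=1.0)  # undefined at x = 0


class TestFitTuning:
    def test_exact_recovery_on_noise_free_data(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-180, 180, 500)
        y = t.dog_curve(x, t.DoGParams(-3.0, 0.02))
        fit = t.fit_tuning(x, y, "dog")
        assert fit.params.a == pytest.approx(-3.0, abs=1e-6)
        assert fit.params.w == pytest.approx(0.02, abs=1e-6)
        assert fit.sse < 1e-6
        assert fit.peak_to_peak == pytest.approx(-6.0, abs=1e-4)

    def test_zero_data_gives_zero_amplitude(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-180, 180, 200)
        fit = t.fit_tuning(x, np.zeros(200), "dog")
        assert abs(fit.params.a) < 1e-9 and abs(fit.peak_to_peak) < 1e-9

    def test_noisy_recovery_small_ensemble(self):
        hits = 0
        for seed in range(5):
            x, y = make_xy(seed=100 + seed, n=1000, amplitude=3.0)
            fit = t.fit_tuning(x, y, "dog")
            hits += 2.4 <= fit.params.a <= 3.6
        assert hits >= 4

    def test_clifford_noise_free_recovery(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-180, 180, 400)
        truth = t.CliffordParams(0.85, 0.12, -1)
        fit = t.fit_tuning(x, t.clifford_curve(x, truth), "clifford")
        assert fit.sse < 1e-6
        assert fit.params.sign * fit.params.s_scale == pytest.approx(-0.85, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            t.fit_tuning(np.arange(10.0), np.arange(10.0), "dog")

    def test_pooled_fit_consistent_with_subject_mean(self):
        # four subjects sharing one bias: pooled amplitude ~ mean of
        # per-subject amplitudes
        per_subject = []
        xs, ys = [], []
        for seed in range(4):
            x, y = make_xy(seed=300 + seed, n=1500, amplitude=2.0)
            per_subject.append(t.fit_tuning(x, y, "dog").params.a)
            xs.append(x)
            ys.append(y)
        pooled = t.fit_tuning(np.concatenate(xs), np.concatenate(ys), "dog")
        assert pooled.params.a == pytest.approx(np.mean(per_subject), abs=0.5)


class TestPeakToPeak:
    def test_dog_analytic_value(self):
        fit = t.fit_tuning(*_exact_dog(3.0, 0.02), model="dog")
        assert fit.peak_to_peak == pytest.approx(6.0, abs=1e-4)

    def test_negative_amplitude_gives_negative_sign(self):
        fit = t.TuningFit("dog", t.DoGParams(-1.5, 0.02), 0.0, 0.0, 100)
        assert t.peak_to_peak(fit) == pytest.approx(-3.0, abs=1e-4)

    def test_flat_curve_is_zero(self):
        fit = t.TuningFit("dog", t.DoGParams(0.0, 0.02), 0.0, 0.0, 100)
        assert t.peak_to_peak(fit) == 0.0

    def test_analytic_identity_matches_grid(self):
        for a in (-4.0, -0.5, 1.0, 6.0):
            for w in (0.005, 0.02, 0.1):
                fit = t.TuningFit("dog", t.DoGParams(a, w), 0.0, 0.0, 100)
                grid_val = t.peak_to_peak(fit)
                analytic = float(t.dog_peak_to_peak_analytic(a, w))
                assert grid_val == pytest.approx(analytic, abs=1e-6)


def _exact_dog(a, w, n=400, seed=3):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-180, 180, n)
    return x, t.dog_curve(x, t.DoGParams(a, w))


class TestMovingAverage:
    def test_constant_signal(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-180, 180, 500)
        out = t.moving_average(x, np.full(500, 5.0), window_deg=20)
        filled = out["count"] > 1
        assert np.allclose(out["mean"][filled], 5.0)
        assert np.allclose(out["sem"][filled], 0.0)

    def test_full_window_equals_global_mean(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-180, 180, 300)
        y = rng.normal(0, 3, 300)
        out = t.moving_average(x, y, window_deg=360.0)
        assert np.allclose(out["mean"], y.mean())

    def test_empty_bins_are_nan(self):
        out = t.moving_average(np.array([0.0, 1.0]), np.array([2.0, 2.0]), window_deg=4)
        far = np.abs(out["grid"]) > 100
        assert np.all(np.isnan(out["mean"][far]))

    def test_recovers_bias_sign(self):
        x, y = make_xy(seed=6, n=5000, amplitude=3.0)
        out = t.moving_average(x, y, window_deg=20)
        near = (out["grid"] > 10) & (out["grid"] < 60)
        assert np.nanmean(out["mean"][near]) > 0


class TestVariancePowerLaw:
    DELAYS = np.array([0.0, 1.0, 3.0, 6.0, 10.0])

    def test_exact_recovery_from_noise_free_curve(self):
        v = 10.0 * (self.DELAYS + 1.0) ** 0.47
        fit = t.fit_variance_power_law(self.DELAYS, v)
        assert fit.beta == pytest.approx(0.47, abs=0.01)
        assert fit.sse < 1e-12

    def test_linear_data_not_worse_under_line(self):
        v = 3.0 * self.DELAYS + 20.0
        fit = t.fit_variance_power_law(self.DELAYS, v)
        assert fit.sse_linear <= fit.sse + 1e-9

    def test_constant_variance_gives_zero_exponent(self):
        fit = t.fit_variance_power_law(self.DELAYS, np.full(5, 30.0))
        assert abs(fit.beta * np.log((10 + fit.t_offset) / fit.t_offset)) < 0.01

    def test_guards(self):
        with pytest.raises(ValueError):
            t.fit_variance_power_law([0, 1], [1.0, 2.0])
        with pytest.raises(ValueError):
            t.fit_variance_power_law(self.DELAYS, [1, 2, 3, -1, 5])
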