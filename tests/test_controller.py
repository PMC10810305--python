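"""Controller chain: envelope extraction against an independent direct-form
filter oracle, calibration, deadband/saturation, and the torque map."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from myoexo.controller import (
    CalibrationResult,
    ControllerConfig,
    MyoelectricController,
    TransmissionSpec,
    calibrate,
    command_current,
    current_to_torque,
    preprocess_emg,
)
from myoexo.signals import SampledSignal

# ---------------------------------------------------------------------------
# independent oracle: hand-derived bilinear-transform Butterworth biquads,
# evaluated with a scalar direct-form-II-transposed loop
# ---------------------------------------------------------------------------


def _biquad_coeffs(kind: str, fc: float, fs: float):
    """2nd-order Butterworth via analog prototype 1/(s^2 + sqrt2 s + 1) and
    the bilinear transform with frequency pre-warp."""
    k = np.tan(np.pi * fc / fs)
    d = 1 + np.sqrt(2) * k + k * k
    a = [1.0, 2 * (k * k - 1) / d, (1 - np.sqrt(2) * k + k * k) / d]
    if kind == "low":
        b = [k * k / d, 2 * k * k / d, k * k / d]
    else:
        b = [1 / d, -2 / d, 1 / d]
    return b, a


def _df2t(x, b, a):
    y = np.empty_like(x)
    z1 = z2 = 0.0
    for i, xi in enumerate(x):
        yi = b[0] * xi + z1
        z1 = b[1] * xi - a[1] * yi + z2
        z2 = b[2] * xi - a[2] * yi
        y[i] = yi
    return y


def oracle_envelope(x: np.ndarray, fs: float, hp: float = 50.0, lp: float = 8.0):
    y = _df2t(x, *_biquad_coeffs("high", hp, fs))
    return np.clip(_df2t(np.abs(y), *_biquad_coeffs("low", lp, fs)), 0.0, None)


class TestPreprocess:
    FS = 1000.0

    def _env(self, values, cfg=None):
        return preprocess_emg(SampledSignal(self.FS, values, "mV"), cfg or ControllerConfig())

    def test_dc_input_rejected_by_highpass(self):
        env = self._env(np.ones(4000))
        assert np.all(env.values[2000:] < 1e-3)

    def test_matches_direct_form_oracle_on_sinusoid(self):
        t = np.arange(8000) / self.FS
        x = np.sin(2 * np.pi * 100.0 * t)
        ours = self._env(x).values
        ref = oracle_envelope(x, self.FS)
        assert np.max(np.abs(ours - ref)) < 1e-6

    def test_steady_state_envelope_of_passband_sinusoid(self):
        """Rectified-sine mean is 2/pi; the 100 Hz carrier sits in the HP
        passband, so the envelope settles near 2/pi times the HP gain."""
        t = np.arange(20000) / self.FS
        x = np.sin(2 * np.pi * 100.0 * t)
        env = self._env(x).values[10000:]
        from scipy.signal import butter, sosfreqz

        sos = butter(2, 50.0, btype="high", fs=self.FS, output="sos")
        gain = np.abs(sosfreqz(sos, worN=[100.0], fs=self.FS)[1][0])
        assert env.mean() == pytest.approx(2 / np.pi * gain, rel=0.02)

    def test_subcutoff_sinusoid_heavily_attenuated(self):
        t = np.arange(20000) / self.FS
        hi = self._env(np.sin(2 * np.pi * 100.0 * t)).values[10000:].mean()
        lo = self._env(np.sin(2 * np.pi * 10.0 * t)).values[10000:].mean()
        assert lo < 0.10 * hi

    def test_nan_input_rejected(self):
        x = np.zeros(1000)
        x[10] = np.nan
        with pytest.raises(ValueError):
            self._env(x)

    def test_rate_below_twice_cutoff_rejected(self):
        with pytest.raises(ValueError):
            preprocess_emg(SampledSignal(90.0, np.zeros(1000)), ControllerConfig())

    def test_causality_prefix_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(3000)
        full = self._env(x).values
        k = 1234
        prefix = self._env(x[:k]).values
        np.testing.assert_allclose(full[:k], prefix, atol=1e-12)


class TestCalibrate:
    def _sig(self, peak, n=15000, rate=1000.0):
        t = np.arange(n) / rate
        return SampledSignal(rate, peak * 0.5 * (1 - np.cos(2 * np.pi * 0.9 * t)), "mV")

    def test_gain_from_max_envelope(self):
        cal = calibrate(self._sig(0.38), ControllerConfig())
        assert cal.gain == pytest.approx(7.6 / 0.38)
        assert cal.threshold == pytest.approx(0.05 * 0.38)

    def test_unit_gain_when_max_is_cap(self):
        cal = calibrate(self._sig(7.6), ControllerConfig())
        assert cal.gain == pytest.approx(1.0)

    def test_calibration_window_reaches_cap_exactly(self):
        cfg = ControllerConfig()
        env = self._sig(0.42)
        cal = calibrate(env, cfg)
        cur = command_current(env, cal, cfg)
        assert cur.values.max() == pytest.approx(7.6)

    def test_all_zero_envelope_uncalibratable(self):
        with pytest.raises(ValueError):
            calibrate(SampledSignal(1000.0, np.zeros(15000)), ControllerConfig())

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            calibrate(self._sig(0.4, n=5000), ControllerConfig())


class TestCommandCurrent:
    CFG = ControllerConfig()

    def test_subthreshold_envelope_gives_zero_current(self):
        cal = CalibrationResult(gain=10.0, threshold=0.5, reference_max=1.0)
        env = SampledSignal(1000.0, np.full(100, 0.4))
        assert np.all(command_current(env, cal, self.CFG).values == 0.0)

    def test_saturation_at_cap(self):
        cal = CalibrationResult(gain=10.0, threshold=0.0, reference_max=1.0)
        env = SampledSignal(1000.0, np.array([1.0]))  # 10 A demanded
        assert command_current(env, cal, self.CFG).values[0] == 7.6

    def test_linear_region_passthrough(self):
        cal = CalibrationResult(gain=10.0, threshold=0.1, reference_max=1.0)
        env = SampledSignal(1000.0, np.array([0.38]))
        assert command_current(env, cal, self.CFG).values[0] == pytest.approx(3.8)

    @given(st.lists(st.floats(0, 2), min_size=1, max_size=50))
    def test_current_always_within_bounds(self, vals):
        cal = CalibrationResult(gain=10.0, threshold=0.05, reference_max=1.0)
        cur = command_current(SampledSignal(1000.0, np.array(vals)), cal, self.CFG).values
        assert np.all((cur >= 0) & (cur <= 7.6))

    @given(st.lists(st.floats(0.1, 0.7), min_size=2, max_size=30), st.floats(0.01, 0.3))
    def test_pointwise_monotonicity(self, vals, bump):
        """A pointwise-larger envelope (above deadband, below saturation)
        never commands less current."""
        cal = CalibrationResult(gain=10.0, threshold=0.05, reference_max=1.0)
        a = np.array(vals)
        b = np.clip(a + bump, None, 0.75)
        ca = command_current(SampledSignal(1000.0, a), cal, self.CFG).values
        cb = command_current(SampledSignal(1000.0, b), cal, self.CFG).values
        assert np.all(cb >= ca)


class TestTorqueMap:
    def test_zero_current_zero_torque(self):
        cfg = ControllerConfig()
        cur = SampledSignal(1000.0, np.zeros(10), "A")
        assert np.all(current_to_torque(cur, None, cfg).values == 0.0)

    def test_constant_ratio(self):
        cfg = ControllerConfig(
            transmission=TransmissionSpec(constant_nm_per_a=2.0))
        cur = SampledSignal(1000.0, np.array([7.6]), "A")
        assert current_to_torque(cur, None, cfg).values[0] == pytest.approx(15.2)

    def test_tabulated_ratio_clamped_at_hull_edge(self):
        cfg = ControllerConfig(transmission=TransmissionSpec(
            constant_nm_per_a=None,
            angles_deg=[-10.0, 10.0], ratios_nm_per_a=[1.0, 3.0]))
        cur = SampledSignal(100.0, np.array([2.0, 2.0]), "A")
        ang = SampledSignal(100.0, np.array([-50.0, 50.0]), "deg")
        tau = current_to_torque(cur, ang, cfg).values
        assert tau[0] == pytest.approx(2.0)   # edge ratio 1.0
        assert tau[1] == pytest.approx(6.0)   # edge ratio 3.0

    def test_negative_table_ratio_rejected_at_load(self):
        with pytest.raises(Exception):
            TransmissionSpec(constant_nm_per_a=None,
                             angles_deg=[0.0, 10.0], ratios_nm_per_a=[1.0, -1.0])

    def test_tabulated_without_angle_rejected(self):
        cfg = ControllerConfig(transmission=TransmissionSpec(
            constant_nm_per_a=None,
            angles_deg=[0.0, 10.0], ratios_nm_per_a=[1.0, 2.0]))
        with pytest.raises(ValueError):
            current_to_torque(SampledSignal(100.0, np.ones(3)), None, cfg)


class TestConfig:
    def test_cutoff_ordering_enforced(self):
        with pytest.raises(Exception):
            ControllerConfig(hp_cutoff=5.0, lp_cutoff=8.0)

    def test_json_round_trip_is_exact(self):
        cfg = ControllerConfig(threshold_fraction=0.07,
                               transmission=TransmissionSpec(constant_nm_per_a=1.9))
        again = ControllerConfig.model_validate_json(cfg.model_dump_json())
        assert again == cfg

    def test_uncalibrated_controller_refuses_to_run(self):
        ctl = MyoelectricController()
        with pytest.raises(RuntimeError):
            ctl.apply(SampledSignal(1000.0, np.zeros(100)))
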