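"""Stride events, cycle normalization, power/work math and the ankle
moment decomposition, checked against closed forms and generator truth."""

import numpy as np
import pytest

from myoexo.biomech import (
    angle_extremes,
    cycle_velocity,
    decompose_ankle,
    detect_events,
    joint_power,
    rom_comparison,
    select_window,
    time_normalize,
    velocity_from_signal,
    work_decomposition,
)
from myoexo.signals import CYCLE_GRID, CycleEnsemble, SampledSignal, StrideEvents
from myoexo.synthetic import GeneratorConfig, generate_trial

from conftest import short_timeline


def square_gait_grf(n_strides=40, rate=100.0, stride_s=1.0, stance=0.6, amp=700.0):
    """Idealized rectangular GRF: amp during stance, 0 during swing."""
    n = int(n_strides * stride_s * rate)
    t = np.arange(n) / rate
    phase = (t / stride_s) % 1.0
    return SampledSignal(rate, np.where(phase < stance, amp, 0.0), "N")


class TestDetectEvents:
    def test_all_zero_grf_gives_no_events(self):
        sig = SampledSignal(100.0, np.zeros(1000), "N")
        with pytest.warns(UserWarning):
            ev = detect_events(sig)
        assert ev.n_strides == 0

    def test_threshold_above_max_gives_no_events(self):
        sig = square_gait_grf(5)
        with pytest.warns(UserWarning):
            ev = detect_events(sig, threshold_n=1e5)
        assert ev.n_strides == 0

    def test_rectangular_gait_recovered_exactly(self):
        # the signal starts mid-stance, so the first stride has no onset
        ev = detect_events(square_gait_grf(11))
        assert ev.n_strides == 9
        np.testing.assert_allclose(np.diff(ev.heel_strike_times), 1.0, atol=0.02)

    def test_generator_ground_truth_recovered(self):
        cfg = GeneratorConfig(n_subjects=1, seed=13, timeline=short_timeline())
        tr = generate_trial(cfg, 0, "Unpowered")
        det = detect_events(tr.channels["grf_v"])
        gt = tr.events
        n = min(det.heel_strikes.size, gt.heel_strikes.size)
        assert np.abs(det.heel_strikes[:n] - gt.heel_strikes[:n]).max() <= 1


class TestSelectWindow:
    EV = detect_events(square_gait_grf(37))  # 35 complete strides

    def test_last_30_of_35(self):
        w = select_window(self.EV, "last", 30)
        assert w.n_strides == 30
        np.testing.assert_array_equal(w.heel_strikes, self.EV.heel_strikes[5:])

    def test_first_30_of_exactly_30(self):
        ev30 = self.EV.subset(0, 30)
        w = select_window(ev30, "first", 30)
        np.testing.assert_array_equal(w.heel_strikes, ev30.heel_strikes)

    def test_shortfall_is_an_error_naming_counts(self):
        ev10 = self.EV.subset(0, 10)
        with pytest.raises(ValueError, match="10"):
            select_window(ev10, "last", 30)

    def test_bad_end_keyword(self):
        with pytest.raises(ValueError):
            select_window(self.EV, "middle", 5)


class TestTimeNormalize:
    EV = detect_events(square_gait_grf(11))

    def test_constant_signal_constant_cycles(self):
        sig = SampledSignal(100.0, np.full(1100, 4.2))
        ens = time_normalize(sig, self.EV)
        np.testing.assert_allclose(ens.curves, 4.2)

    def test_linear_ramp_is_exact_under_interpolation(self):
        sig = SampledSignal(100.0, np.arange(1100, dtype=float))
        ens = time_normalize(sig, self.EV)
        for row in ens.curves:
            np.testing.assert_allclose(np.diff(row, 2), 0.0, atol=1e-9)

    def test_thirty_strides_give_thirty_curves(self):
        ev = detect_events(square_gait_grf(32))
        sig = SampledSignal(100.0, np.random.default_rng(0).standard_normal(3200))
        ens = time_normalize(sig, select_window(ev, "last", 30))
        assert ens.n_strides == 30
        assert ens.curves.shape == (30, 101)

    def test_cross_clock_normalization(self):
        """EMG-clock signals normalize against mechanics-clock events."""
        sig = SampledSignal(1000.0, np.arange(11000, dtype=float))
        ens = time_normalize(sig, self.EV)
        assert ens.n_strides == self.EV.n_strides

    def test_stance_end_recorded(self):
        sig = SampledSignal(100.0, np.zeros(1100))
        ens = time_normalize(sig, self.EV)
        np.testing.assert_allclose(ens.stance_end, 60.0, atol=2.0)


def one_stride(curve, duration=1.0, stance=60.0, units=""):
    return CycleEnsemble(curve[None, :], np.array([stance]), np.array([duration]), units)


class TestJointPower:
    S = CYCLE_GRID / 100.0

    def test_constant_angle_zero_power(self):
        p = joint_power(one_stride(np.ones(101)), one_stride(np.full(101, 30.0)))
        np.testing.assert_allclose(p.curves, 0.0, atol=1e-12)

    def test_sinusoid_closed_form(self):
        """angle sin(2*pi*s) deg, moment cos(2*pi*s) over a 1 s stride:
        P = 2*pi*cos^2(2*pi*s) * pi/180 (finite-difference tolerance)."""
        ang = one_stride(np.sin(2 * np.pi * self.S))
        mom = one_stride(np.cos(2 * np.pi * self.S))
        p = joint_power(mom, ang).curves[0]
        expect = 2 * np.pi * np.cos(2 * np.pi * self.S) ** 2 * np.pi / 180
        np.testing.assert_allclose(p[1:-1], expect[1:-1], rtol=0.01, atol=1e-4)

    def test_zero_moment_zero_power(self):
        p = joint_power(one_stride(np.zeros(101)), one_stride(np.sin(self.S)))
        np.testing.assert_allclose(p.curves, 0.0)

    def test_time_domain_velocity_matches_grid_on_smooth_signal(self):
        rate, stride = 100.0, 1.0
        n = int(12 * stride * rate)
        t = np.arange(n) / rate
        ang = SampledSignal(rate, 10 * np.sin(2 * np.pi * t / stride), "deg")
        ev = detect_events(square_gait_grf(12, rate, stride))
        v_time = velocity_from_signal(ang, ev)
        v_grid = cycle_velocity(time_normalize(ang, ev))
        np.testing.assert_allclose(
            v_time.curves[:, 2:-2], v_grid.curves[:, 2:-2], rtol=0.03, atol=0.01)


class TestWork:
    S = CYCLE_GRID / 100.0

    def test_unit_power_unit_positive_work(self):
        wp, wn = work_decomposition(one_stride(np.ones(101), duration=1.0))
        assert wp == pytest.approx(1.0)
        assert wn == 0.0

    def test_sinusoid_positive_and_negative_lobes(self):
        wp, wn = work_decomposition(one_stride(np.sin(2 * np.pi * self.S)))
        assert wp == pytest.approx(1 / np.pi, rel=0.005)
        assert wn == pytest.approx(-1 / np.pi, rel=0.005)

    def test_nonpositive_power_gives_no_positive_work(self):
        wp, _ = work_decomposition(one_stride(-np.abs(np.sin(self.S))))
        assert wp == 0.0


class TestDecomposition:
    def _tri(self, peak, center=50, width=20):
        return peak * np.clip(1 - np.abs(CYCLE_GRID - center) / width, 0, None)

    def test_zero_exo_torque_zero_shares(self):
        dec = decompose_ankle(
            one_stride(self._tri(1.5), units="Nm/kg"),
            one_stride(np.zeros(101), units="Nm"),
            70.0, one_stride(-10 * np.sin(2 * np.pi * CYCLE_GRID / 100)))
        assert dec.peak_moment_share == 0.0
        assert dec.peak_power_share == 0.0
        assert dec.positive_work_share == 0.0

    def test_cotimed_triangles_moment_share(self):
        mass = 70.0
        total = one_stride(self._tri(2.0), units="Nm/kg")
        exo = one_stride(self._tri(0.5) * mass, units="Nm")
        dec = decompose_ankle(total, exo, mass,
                              one_stride(np.sin(2 * np.pi * CYCLE_GRID / 100)))
        assert dec.peak_moment_share == pytest.approx(0.25)
        np.testing.assert_allclose(dec.bio_moment.mean.max(), 1.5)

    def test_conservation_total_is_bio_plus_exo(self):
        rng = np.random.default_rng(8)
        total = one_stride(rng.standard_normal(101), units="Nm/kg")
        exo = one_stride(np.abs(rng.standard_normal(101)), units="Nm")
        ang = one_stride(rng.standard_normal(101))
        dec = decompose_ankle(total, exo, 70.0, ang)
        np.testing.assert_allclose(
            dec.bio_moment.curves + dec.exo_moment.curves, dec.total_moment.curves,
            atol=1e-12)
        np.testing.assert_allclose(
            dec.bio_power.curves + dec.exo_power.curves, dec.total_power.curves,
            atol=1e-12)

    def test_positive_work_superadditive_for_cosigned_components(self):
        total = one_stride(self._tri(2.0), units="Nm/kg")
        exo = one_stride(self._tri(0.5) * 70.0, units="Nm")
        ang = one_stride(np.sin(2 * np.pi * CYCLE_GRID / 100))
        dec = decompose_ankle(total, exo, 70.0, ang)
        assert dec.work_pos["total"] >= max(dec.work_pos["bio"], dec.work_pos["exo"]) - 1e-12

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            decompose_ankle(one_stride(np.ones(101)), one_stride(np.ones(101)),
                            0.0, one_stride(np.ones(101)))


class TestRomComparison:
    def test_identical_sources_no_difference(self):
        diffs, avg = rom_comparison([(5, 20)], [(5, 20)])
        assert avg == 0.0

    def test_unpowered_printed_endpoints(self):
        diffs, _ = rom_comparison([(5, 20)], [(7, 4)])
        assert diffs[0] == pytest.approx(14.0)

    def test_three_condition_average(self):
        bio = [(5, 20), (8, 14), (8, 14)]
        exo = [(7, 4), (2.5, 6), (2.5, 7)]
        diffs, avg = rom_comparison(bio, exo)
        np.testing.assert_allclose(diffs, [14.0, 13.5, 12.5])
        assert avg == pytest.approx(13.333, abs=0.01)

    def test_negative_magnitudes_rejected(self):
        with pytest.raises(ValueError):
            rom_comparison([(-5, 20)], [(7, 4)])

    def test_angle_extremes_sign_conventions(self):
        ens = one_stride(np.concatenate([np.full(50, 8.0), np.full(51, -14.0)]))
        df, pf = angle_extremes(ens, dorsiflexion_positive=True)
        assert (df, pf) == (8.0, 14.0)


class TestGridInvariance:
    def test_doubling_mechanics_rate_barely_moves_cycle_means(self):
        cfg100 = GeneratorConfig(n_subjects=1, seed=5, timeline=short_timeline())
        cfg200 = cfg100.model_copy(update={"sample_rate_mech": 200.0})
        m = {}
        for cfg in (cfg100, cfg200):
            # ground-truth events isolate normalization from detector rounding
            tr = generate_trial(cfg, 0, "Unpowered")
            ens = time_normalize(tr.channels["ankle_angle"],
                                 select_window(tr.events, "last", 30))
            m[cfg.sample_rate_mech] = ens.mean
        span = np.ptp(m[100.0])
        assert np.max(np.abs(m[100.0] - m[200.0])) / span < 0.01
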