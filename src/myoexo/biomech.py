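"""Stride segmentation, cycle normalization, and joint power/work analysis.

Gait cycles run heel contact (0%) to the next ipsilateral heel contact
(100%) on a 101-point grid.  Joint power is moment times angular velocity;
the decomposition splits the total ankle moment into the exoskeleton's
contribution (commanded torque over body mass) and the biological
remainder, and reports the device's share of peak moment, peak power and
positive work over the stride.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .signals import CYCLE_GRID, CYCLE_POINTS, CycleEnsemble, SampledSignal, StrideEvents

DEG2RAD = np.pi / 180.0


def detect_events(
    grf_v: SampledSignal,
    threshold_n: float = 20.0,
    min_interval_s: float = 0.4,
) -> StrideEvents:
    """Heel strikes / toe-offs from the vertical ground reaction force.

    Heel strike is an upward crossing of ``threshold_n``, toe-off a downward
    crossing.  Upward crossings closer than ``min_interval_s`` to the
    previous accepted one are treated as chatter and dropped; between each
    pair of accepted heel strikes the last downward crossing is kept as the
    toe-off.
    """
    v = grf_v.values
    above = v >= threshold_n
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    down = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    if up.size == 0:
        warnings.warn("no threshold crossings in GRF; returning empty events")
        return StrideEvents(np.array([], int), np.array([], int), grf_v.rate)

    min_gap = int(min_interval_s * grf_v.rate)
    hs = [int(up[0])]
    for i in up[1:]:
        if i - hs[-1] >= min_gap:
            hs.append(int(i))
    hs = np.asarray(hs, int)

    to = []
    for a, b in zip(hs[:-1], hs[1:]):
        inside = down[(down > a) & (down < b)]
        if inside.size == 0:
            warnings.warn(f"no toe-off between heel strikes at samples {a} and {b}")
            continue
        to.append(int(inside[-1]))
    # drop heel strikes whose stride lacks a toe-off
    if len(to) < hs.size - 1:
        keep = [hs[0]]
        ti = 0
        for a, b in zip(hs[:-1], hs[1:]):
            inside = down[(down > a) & (down < b)]
            if inside.size:
                keep.append(int(b))
        hs = np.asarray(keep, int)
    return StrideEvents(hs, np.asarray(to, int), grf_v.rate)


def select_window(events: StrideEvents, end: str = "last", n: int = 30) -> StrideEvents:
    """The first or last ``n`` contiguous complete strides of a bout."""
    if end not in ("first", "last"):
        raise ValueError("end must be 'first' or 'last'")
    if events.n_strides < n:
        raise ValueError(
            f"need {n} complete strides, only {events.n_strides} available"
        )
    return events.subset(0, n) if end == "first" else events.subset(events.n_strides - n, events.n_strides)


def time_normalize(signal: SampledSignal, events: StrideEvents) -> CycleEnsemble:
    """Resample each stride onto the 101-point gait-cycle grid.

    Linear interpolation against the signal's own clock, so the event train
    may live on a different (e.g. mechanics) clock than the signal.  Strides
    covering fewer than 3 samples of ``signal`` are skipped with a warning.
    """
    t = signal.times
    curves, stance_end, durations = [], [], []
    for t0, t_to, t1 in events.stride_spans():
        if t1 > signal.duration + 0.5 / signal.rate or (t1 - t0) * signal.rate < 3:
            warnings.warn("stride outside signal span or shorter than 3 samples; skipped")
            continue
        grid_t = t0 + (CYCLE_GRID / 100.0) * (t1 - t0)
        curves.append(np.interp(grid_t, t, signal.values))
        stance_end.append(100.0 * (t_to - t0) / (t1 - t0))
        durations.append(t1 - t0)
    if not curves:
        raise ValueError("no usable strides in the event train")
    return CycleEnsemble(np.array(curves), np.array(stance_end), np.array(durations), signal.units)


def cycle_velocity(angle: CycleEnsemble) -> CycleEnsemble:
    """Angular velocity (rad/s) of an angle ensemble (deg) by centered differences."""
    ds = (angle.durations / (CYCLE_POINTS - 1))[:, None]  # seconds per grid step
    vel = np.gradient(angle.curves * DEG2RAD, axis=1) / ds
    return CycleEnsemble(vel, angle.stance_end, angle.durations, "rad/s")


def velocity_from_signal(angle: SampledSignal, events: StrideEvents) -> CycleEnsemble:
    """Angular velocity computed on the time-domain angle, then normalized.

    Differentiating before time-normalization avoids the cadence-dependent
    bias of differencing on the resampled grid.
    """
    vel = SampledSignal(
        angle.rate, np.gradient(angle.values * DEG2RAD) * angle.rate, "rad/s"
    )
    return time_normalize(vel, events)


def joint_power(
    moment: CycleEnsemble, angle: CycleEnsemble, velocity: Optional[CycleEnsemble] = None
) -> CycleEnsemble:
    """Joint power (W/kg) = moment (Nm/kg) x angular velocity (rad/s).

    Moment and angle must share sign conventions (a positive moment doing
    positive work on a positively increasing angle).  Pass a precomputed
    ``velocity`` ensemble to use time-domain differentiation; otherwise the
    velocity comes from centered differences of ``angle`` on the cycle grid.
    """
    if moment.curves.shape != angle.curves.shape:
        raise ValueError("moment and angle ensembles must share shape")
    if moment.durations.size == 0 or np.any(~np.isfinite(moment.durations)):
        raise ValueError("stride durations are required for power")
    vel = velocity if velocity is not None else cycle_velocity(angle)
    return CycleEnsemble(
        moment.curves * vel.curves, moment.stance_end, moment.durations, "W/kg"
    )


def work_decomposition(power: CycleEnsemble) -> tuple[float, float]:
    """Mean positive and negative work (J/kg) per stride.

    Trapezoid integration of max(P,0) and min(P,0) over stride time,
    averaged across the ensemble's strides.
    """
    s = CYCLE_GRID / 100.0
    wpos = np.array([
        np.trapezoid(np.clip(row, 0.0, None), s * d)
        for row, d in zip(power.curves, power.durations)
    ])
    wneg = np.array([
        np.trapezoid(np.clip(row, None, 0.0), s * d)
        for row, d in zip(power.curves, power.durations)
    ])
    return float(wpos.mean()), float(wneg.mean())


@dataclass
class AnkleDecomposition:
    """Exoskeleton / biological / total ankle curves and contribution shares.

    Moments in Nm/kg, powers in W/kg, works in J/kg.  ``total = bio + exo``
    pointwise for the moment curves and for the power curves in the
    biological-angle frame.  ``exo_power_device`` is the device-frame power
    (exoskeleton angle velocity), reported alongside because the device's
    own angle shows a smaller range of motion than the biological ankle.
    Shares are peak-of-mean-curve ratios; the work share is positive work.
    """

    exo_moment: CycleEnsemble
    bio_moment: CycleEnsemble
    total_moment: CycleEnsemble
    exo_power: CycleEnsemble
    bio_power: CycleEnsemble
    total_power: CycleEnsemble
    exo_power_device: Optional[CycleEnsemble]
    work_pos: dict = field(default_factory=dict)   # component -> J/kg
    work_neg: dict = field(default_factory=dict)
    peak_power_share: float = 0.0
    peak_moment_share: float = 0.0
    positive_work_share: float = 0.0


def decompose_ankle(
    total_moment: CycleEnsemble,
    exo_torque: CycleEnsemble,
    body_mass_kg: float,
    angle: CycleEnsemble,
    exo_angle: Optional[CycleEnsemble] = None,
    velocity: Optional[CycleEnsemble] = None,
    use_exo_angle: bool = False,
) -> AnkleDecomposition:
    """Split the total ankle moment/power into device and biological parts.

    ``total_moment`` is the combined (inverse-dynamics) ankle moment in
    Nm/kg; ``exo_torque`` the commanded device torque in Nm, divided by
    ``body_mass_kg`` for comparability.  ``angle`` must be in the same sign
    convention as the moment (plantarflexion-positive here).  The
    biological moment is total minus exoskeleton, pointwise.

    By default every power component uses the biological-angle velocity, so
    total power = bio + exo power exactly; ``use_exo_angle=True`` makes the
    headline exo power the device-frame one instead.
    """
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    exo_m = exo_torque.scaled(1.0 / body_mass_kg)
    exo_m.units = "Nm/kg"
    if exo_m.curves.shape != total_moment.curves.shape:
        raise ValueError("exo torque and total moment ensembles must share shape")
    bio_m = CycleEnsemble(
        total_moment.curves - exo_m.curves,
        total_moment.stance_end, total_moment.durations, "Nm/kg",
    )
    vel = velocity if velocity is not None else cycle_velocity(angle)
    total_p = joint_power(total_moment, angle, vel)
    bio_p = joint_power(bio_m, angle, vel)
    exo_p_bio = joint_power(exo_m, angle, vel)
    exo_p_dev = None
    if exo_angle is not None:
        exo_p_dev = joint_power(exo_m, exo_angle)
    exo_p = exo_p_dev if (use_exo_angle and exo_p_dev is not None) else exo_p_bio

    work_pos, work_neg = {}, {}
    for name, p in (("exo", exo_p), ("bio", bio_p), ("total", total_p)):
        wp, wn = work_decomposition(p)
        work_pos[name], work_neg[name] = wp, wn

    def _peak(e: CycleEnsemble) -> float:
        return float(e.mean.max())

    tot_peak_m, tot_peak_p = _peak(total_moment), _peak(total_p)
    dec = AnkleDecomposition(
        exo_moment=exo_m, bio_moment=bio_m, total_moment=total_moment,
        exo_power=exo_p, bio_power=bio_p, total_power=total_p,
        exo_power_device=exo_p_dev,
        work_pos=work_pos, work_neg=work_neg,
        peak_moment_share=_peak(exo_m) / tot_peak_m if tot_peak_m > 0 else 0.0,
        peak_power_share=_peak(exo_p) / tot_peak_p if tot_peak_p > 0 else 0.0,
        positive_work_share=(
            work_pos["exo"] / work_pos["total"] if work_pos["total"] > 0 else 0.0
        ),
    )
    return dec


def rom_comparison(
    bio_extremes: Sequence[tuple[float, float]],
    exo_extremes: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, float]:
    """Range-of-motion discrepancy between angle sources, per condition.

    Each extreme is a (max dorsiflexion, max plantarflexion) pair of
    positive magnitudes in degrees.  ROM = DF + PF per source; the
    difference is biological minus device ROM, averaged across conditions.
    """
    bio = np.asarray(bio_extremes, float)
    exo = np.asarray(exo_extremes, float)
    if bio.shape != exo.shape or bio.ndim != 2 or bio.shape[1] != 2:
        raise ValueError("extremes must be matched (DF, PF) pairs per condition")
    if np.any(bio < 0) or np.any(exo < 0):
        raise ValueError("extremes are magnitudes and must be non-negative")
    diff = bio.sum(axis=1) - exo.sum(axis=1)
    return diff, float(diff.mean())


def angle_extremes(angle: CycleEnsemble, dorsiflexion_positive: bool = True) -> tuple[float, float]:
    """(max dorsiflexion, max plantarflexion) magnitudes of a mean angle curve."""
    m = angle.mean
    if dorsiflexion_positive:
        return float(max(m.max(), 0.0)), float(max(-m.min(), 0.0))
    return float(max(-m.min(), 0.0)), float(max(m.max(), 0.0))
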