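"""Synthetic multi-subject gait and surface-EMG generator.

Emulates a single-session treadmill protocol with an ankle exoskeleton:
Boots Only (5 min), Unpowered (5 min), Powered (30 min), Deadaptation
(10 min).  Each trial carries four EMG channels (soleus, medial/lateral
gastrocnemius, tibialis anterior) on a 1000 Hz clock and sagittal
ankle/knee/hip angles and moments, the exoskeleton's own ankle angle, and
vertical GRF on a 100 Hz mechanics clock.

Muscle envelopes are sums of Gaussian bursts in %-gait-cycle; raw EMG is
that envelope modulating band-limited (20-450 Hz) Gaussian noise.  Practice
with the powered device scales the triceps surae envelopes by an
exponential-approach adaptation factor (down-regulation) and the tibialis
anterior up; after power-off the factor decays back toward baseline.  The
exoskeleton angle is an affine compression of the biological ankle angle,
reproducing the range-of-motion deficit seen when a shank cuff and soft
tissue decouple the device from the joint.

Every draw is keyed off the config seed, so an identical config yields a
byte-identical dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .signals import CYCLE_GRID, CycleEnsemble, SampledSignal, StrideEvents, butter_sos

CONDITIONS = ("BootsOnly", "Unpowered", "Powered", "Deadaptation")
MUSCLES = ("sol", "mg", "lg", "ta")
GRAVITY = 9.81

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class MuscleBurst(BaseModel):
    """One Gaussian activation burst: center and width (SD) in %cycle, amplitude in mV."""

    center: float
    width: float = Field(gt=0.0)
    amplitude: float = Field(ge=0.0)


class MuscleAdaptation(BaseModel):
    """Practice effect on a muscle's envelope.

    ``steady_state_change`` is the signed fractional change reached after
    long practice (-0.12 = a 12% decrease); ``time_constant_min`` the
    exponential approach time constant in minutes.
    """

    steady_state_change: float = 0.0
    time_constant_min: float = Field(5.0, gt=0.0)


class AngleDiscrepancy(BaseModel):
    """Affine map from biological to device-reported ankle angle (deg)."""

    angle_scale: float = Field(0.44, ge=0.0)
    angle_offset: float = 4.8


class TimelineEntry(BaseModel):
    condition: str
    minutes: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "TimelineEntry":
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        return self


def _default_bursts() -> dict[str, list[MuscleBurst]]:
    mk = lambda *t: [MuscleBurst(center=c, width=w, amplitude=a) for c, w, a in t]
    return {
        # plantar flexors: active throughout stance, push-off dominated
        "sol": mk((15.0, 8.0, 0.10), (47.0, 9.0, 0.38)),
        "mg": mk((42.0, 8.0, 0.42)),
        "lg": mk((43.0, 8.0, 0.32)),
        # dorsiflexor: swing clearance + heel-contact burst (wraps through 0%)
        "ta": mk((70.0, 6.0, 0.22), (2.0, 4.0, 0.28)),
    }


def _default_adaptation() -> dict[str, MuscleAdaptation]:
    return {
        "sol": MuscleAdaptation(steady_state_change=-0.12),
        "mg": MuscleAdaptation(steady_state_change=-0.05),
        "lg": MuscleAdaptation(steady_state_change=-0.17),
        "ta": MuscleAdaptation(steady_state_change=+0.09),
    }


def _default_timeline() -> list[TimelineEntry]:
    return [
        TimelineEntry(condition="BootsOnly", minutes=5.0),
        TimelineEntry(condition="Unpowered", minutes=5.0),
        TimelineEntry(condition="Powered", minutes=30.0),
        TimelineEntry(condition="Deadaptation", minutes=10.0),
    ]


class GeneratorConfig(BaseModel):
    """Everything the generator needs; identical configs give identical data."""

    n_subjects: int = Field(12, ge=1)
    seed: int = 0
    sample_rate_emg: float = Field(1000.0, gt=0.0)
    sample_rate_mech: float = Field(100.0, gt=0.0)
    cadence_mean: float = Field(0.9, gt=0.0)      # strides/s
    cadence_cv: float = Field(0.03, ge=0.0)       # stride-to-stride
    cadence_subject_cv: float = Field(0.05, ge=0.0)
    stance_fraction: float = Field(0.60, gt=0.0, lt=1.0)
    burst_params: dict[str, list[MuscleBurst]] = Field(default_factory=_default_bursts)
    adaptation: dict[str, MuscleAdaptation] = Field(default_factory=_default_adaptation)
    subject_adaptation_sd: float = Field(0.03, ge=0.0)
    discrepancy: AngleDiscrepancy = Field(default_factory=AngleDiscrepancy)
    timeline: list[TimelineEntry] = Field(default_factory=_default_timeline)
    body_mass: float = Field(69.3, gt=0.0)        # kg
    walking_speed: float = Field(1.15, gt=0.0)    # m/s, metadata
    stride_amp_cv: float = Field(0.08, ge=0.0)    # per-stride envelope jitter
    subject_amp_sigma: float = Field(0.2, ge=0.0)  # lognormal sigma of subject gain
    noise_floor_mv: float = Field(0.01, ge=0.0)
    carrier_band: tuple[float, float] = (20.0, 450.0)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if set(self.burst_params) != set(MUSCLES) or set(self.adaptation) != set(MUSCLES):
            raise ValueError(f"burst_params/adaptation must cover exactly {MUSCLES}")
        if not 0 < self.carrier_band[0] < self.carrier_band[1]:
            raise ValueError("carrier band must be increasing and positive")
        return self

    def powered_minutes(self) -> float:
        return sum(e.minutes for e in self.timeline if e.condition == "Powered")

    def total_minutes(self) -> float:
        return sum(e.minutes for e in self.timeline)


@dataclass
class TrialRecording:
    """One subject x condition recording plus its generating ground truth."""

    subject_id: str
    condition: str
    channels: dict[str, SampledSignal]
    events: StrideEvents                 # ground-truth events, mechanics clock
    ground_truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# kinematic / kinetic / GRF templates (dorsiflexion- and flexion-positive deg,
# plantarflexion-positive Nm/kg).  Knots tuned once so the noise-free device
# contribution sits in the target regime (peak exo power ~0.63 W/kg, ~29% of
# peak total ankle power); see docs/methods.md.
# ---------------------------------------------------------------------------

_TEMPLATE_KNOTS = {
    "ankle_angle": [(0, 0.0), (6, -4.0), (18, 2.0), (45, 10.0), (65, -18.0),
                    (78, -4.0), (92, 2.0), (100, 0.0)],
    "ankle_moment": [(0, 0.0), (4, -0.08), (12, 0.15), (30, 0.8), (45, 1.25),
                     (54, 0.50), (62, 0.0), (80, 0.0), (100, 0.0)],
    "knee_angle": [(0, 5.0), (15, 20.0), (42, 6.0), (60, 8.0), (74, 60.0),
                   (90, 22.0), (100, 5.0)],
    "knee_moment": [(0, 0.0), (10, 0.45), (25, -0.2), (50, 0.12), (62, 0.0),
                    (75, -0.12), (90, 0.0), (100, 0.0)],
    "hip_angle": [(0, 30.0), (50, -8.0), (60, -10.0), (85, 32.0), (100, 30.0)],
    "hip_moment": [(0, 0.55), (20, -0.2), (50, -0.7), (60, -0.85), (66, 0.15),
                   (80, 0.05), (100, 0.55)],
}

_TEMPLATES = {
    name: PchipInterpolator(*zip(*[(k, v) for k, v in knots]))
    for name, knots in _TEMPLATE_KNOTS.items()
}


def mechanics_template(name: str, phase: np.ndarray) -> np.ndarray:
    """Evaluate a joint angle/moment template at %cycle phase values."""
    return _TEMPLATES[name](np.mod(phase, 100.0))


def grf_template(phase: np.ndarray, stance_end: float, body_weight_n: float) -> np.ndarray:
    """Vertical GRF: double-bump stance profile, exactly zero in swing.

    ``stance_end`` in %cycle.  Sharp (1.5% of stance) onset/offset ramps
    plus loading/pre-swing shoulders keep the threshold crossings within
    one mechanics sample of the true stance boundaries.
    """
    u = np.asarray(phase, float) / stance_end
    g = lambda c, w: np.exp(-(((u - c) / w) ** 2))
    f = (1.15 * g(0.27, 0.13) + 1.12 * g(0.76, 0.12) + 0.35 * g(0.5, 0.2)
         + 0.30 * g(0.08, 0.06) + 0.12 * g(0.93, 0.05))
    ramp = np.clip(u / 0.015, 0.0, 1.0) * np.clip((1.0 - u) / 0.015, 0.0, 1.0)
    out = body_weight_n * f * ramp
    out[(u <= 0.0) | (u >= 1.0)] = 0.0
    return out


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------


def emg_envelope_template(bursts: list[MuscleBurst], phase_grid: np.ndarray) -> np.ndarray:
    """Sum of Gaussian bursts on a %cycle grid, wrapped circularly at 0/100.

    Circular wrapping keeps bursts centered near heel contact continuous
    across the stride boundary.
    """
    phase = np.asarray(phase_grid, float)
    if np.any((phase < 0) | (phase > 100)):
        raise ValueError("phase grid must lie in [0, 100]")
    env = np.zeros_like(phase)
    for b in bursts:
        if b.amplitude < 0:
            raise ValueError("burst amplitude must be non-negative")
        d = np.mod(phase - b.center + 50.0, 100.0) - 50.0  # circular distance
        env += b.amplitude * np.exp(-0.5 * (d / b.width) ** 2)
    return env


def adaptation_factor(elapsed_powered_minutes, adaptation: MuscleAdaptation):
    """Envelope multiplier after t minutes of powered practice.

    1 + steady_state_change * (1 - exp(-t / tau)); equals 1 at t = 0.
    """
    t = np.asarray(elapsed_powered_minutes, float)
    if np.any(t < 0):
        raise ValueError("elapsed practice time must be >= 0")
    if adaptation.time_constant_min <= 0:
        raise ValueError("time constant must be positive")
    out = 1.0 + adaptation.steady_state_change * (
        1.0 - np.exp(-t / adaptation.time_constant_min)
    )
    return float(out) if np.isscalar(elapsed_powered_minutes) else out


def deadaptation_factor(
    minutes_since_power_off, adaptation: MuscleAdaptation, powered_minutes: float
):
    """Washout multiplier: decays from the end-of-practice level back to 1."""
    t = np.asarray(minutes_since_power_off, float)
    if np.any(t < 0):
        raise ValueError("time since power-off must be >= 0")
    end_change = adaptation.steady_state_change * (
        1.0 - np.exp(-powered_minutes / adaptation.time_constant_min)
    )
    out = 1.0 + end_change * np.exp(-t / adaptation.time_constant_min)
    return float(out) if np.isscalar(minutes_since_power_off) else out


def synthesize_raw_emg(
    envelope: SampledSignal,
    rng: np.random.Generator,
    noise_floor: float = 0.01,
    carrier_band: tuple[float, float] = (20.0, 450.0),
) -> SampledSignal:
    """Raw surface EMG: the envelope modulating band-limited Gaussian noise.

    The carrier is unit-RMS white noise band-passed to ``carrier_band``;
    the effective modulation is sqrt(envelope^2 + floor^2), so an all-zero
    envelope leaves a noise floor of RMS ``noise_floor``.
    """
    if np.any(envelope.values < 0):
        raise ValueError("envelope must be non-negative")
    if envelope.rate < 2.0 * carrier_band[1]:
        raise ValueError(
            f"rate {envelope.rate} Hz aliases a {carrier_band[1]} Hz carrier band"
        )
    sos = sps.butter(4, carrier_band, btype="band", fs=envelope.rate, output="sos")
    carrier = sps.sosfilt(sos, rng.standard_normal(envelope.n))
    carrier /= carrier.std() if carrier.std() > 0 else 1.0
    mod = np.sqrt(envelope.values**2 + noise_floor**2)
    return SampledSignal(envelope.rate, mod * carrier, "mV")


def exo_angle_from_bio(
    bio_angle: SampledSignal, discrepancy: AngleDiscrepancy,
    smooth_cutoff_hz: Optional[float] = None,
) -> SampledSignal:
    """Device-reported ankle angle: affine compression of the biological angle.

    exo = scale * bio + offset, optionally low-pass smoothed.  The default
    scale/offset reproduce the unpowered-walking endpoints (biological 5
    deg DF to 20 deg PF against device 7 deg DF to 4 deg PF).
    """
    if discrepancy.angle_scale < 0:
        raise ValueError("angle scale must be non-negative")
    vals = discrepancy.angle_scale * bio_angle.values + discrepancy.angle_offset
    if smooth_cutoff_hz is not None:
        sos = butter_sos("low", smooth_cutoff_hz, bio_angle.rate)
        vals = sps.sosfiltfilt(sos, vals)
    return SampledSignal(bio_angle.rate, vals, "deg")


# ---------------------------------------------------------------------------
# trial and dataset assembly
# ---------------------------------------------------------------------------


def _subject_params(cfg: GeneratorConfig, subject_idx: int) -> dict:
    rng = np.random.default_rng([cfg.seed, subject_idx, 0])
    amp_scale = float(np.exp(cfg.subject_amp_sigma * rng.standard_normal()))
    cadence = float(cfg.cadence_mean * (1.0 + cfg.cadence_subject_cv * rng.standard_normal()))
    cadence = max(cadence, 0.3 * cfg.cadence_mean)
    adapt = {}
    for m in MUSCLES:
        base = cfg.adaptation[m]
        adapt[m] = MuscleAdaptation(
            steady_state_change=base.steady_state_change
            + cfg.subject_adaptation_sd * float(rng.standard_normal()),
            time_constant_min=base.time_constant_min,
        )
    return {"amp_scale": amp_scale, "cadence": cadence, "adaptation": adapt}


def _stride_timeline(
    cfg: GeneratorConfig, cadence: float, total_s: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(heel-strike start times, stride durations) covering [0, total_s]."""
    mean_dur = 1.0 / cadence
    durs = []
    t = 0.0
    while t < total_s:
        d = mean_dur * max(1.0 + cfg.cadence_cv * float(rng.standard_normal()), 0.2)
        durs.append(d)
        t += d
    durs = np.asarray(durs)
    starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
    return starts, durs


def _phase_of(t: np.ndarray, starts: np.ndarray, durs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, durs.size - 1)
    phase = (t - starts[idx]) / durs[idx] * 100.0
    return np.clip(phase, 0.0, 100.0 - 1e-9), idx


def _condition_amp_factors(
    cfg: GeneratorConfig, condition: str, muscle: str,
    adaptation: MuscleAdaptation, starts: np.ndarray,
) -> np.ndarray:
    """Per-stride adaptation multiplier from protocol time within the condition."""
    if condition == "Powered":
        return adaptation_factor(starts / 60.0, adaptation)
    if condition == "Deadaptation":
        return deadaptation_factor(starts / 60.0, adaptation, cfg.powered_minutes())
    return np.ones_like(starts)


def generate_trial(cfg: GeneratorConfig, subject_idx: int, condition: str) -> TrialRecording:
    """Generate one continuous condition recording for one subject."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    minutes = next(e.minutes for e in cfg.timeline if e.condition == condition)
    total_s = minutes * 60.0
    sp = _subject_params(cfg, subject_idx)
    cond_idx = CONDITIONS.index(condition)

    rng_strides = np.random.default_rng([cfg.seed, subject_idx, cond_idx, 1])
    starts, durs = _stride_timeline(cfg, sp["cadence"], total_s, rng_strides)

    n_mech = int(round(total_s * cfg.sample_rate_mech))
    n_emg = int(round(total_s * cfg.sample_rate_emg))
    t_mech = np.arange(n_mech) / cfg.sample_rate_mech
    t_emg = np.arange(n_emg) / cfg.sample_rate_emg
    ph_mech, _ = _phase_of(t_mech, starts, durs)
    ph_emg, stride_emg = _phase_of(t_emg, starts, durs)

    channels: dict[str, SampledSignal] = {}
    for joint in ("ankle", "knee", "hip"):
        channels[f"{joint}_angle"] = SampledSignal(
            cfg.sample_rate_mech, mechanics_template(f"{joint}_angle", ph_mech), "deg")
        channels[f"{joint}_moment"] = SampledSignal(
            cfg.sample_rate_mech, mechanics_template(f"{joint}_moment", ph_mech), "Nm/kg")
    channels["exo_angle"] = exo_angle_from_bio(channels["ankle_angle"], cfg.discrepancy)
    channels["grf_v"] = SampledSignal(
        cfg.sample_rate_mech,
        grf_template(ph_mech, cfg.stance_fraction * 100.0, cfg.body_mass * GRAVITY),
        "N",
    )

    for mi, muscle in enumerate(MUSCLES):
        base_env = emg_envelope_template(cfg.burst_params[muscle], ph_emg)
        adapt_per_stride = _condition_amp_factors(
            cfg, condition, muscle, sp["adaptation"][muscle], starts)
        rng_jit = np.random.default_rng([cfg.seed, subject_idx, cond_idx, 2, mi])
        jitter = np.exp(
            cfg.stride_amp_cv * rng_jit.standard_normal(starts.size)
            - 0.5 * cfg.stride_amp_cv**2
        )
        amp = sp["amp_scale"] * adapt_per_stride * jitter
        env = SampledSignal(cfg.sample_rate_emg, base_env * amp[stride_emg], "mV")
        rng_car = np.random.default_rng([cfg.seed, subject_idx, cond_idx, 3, mi])
        channels[f"emg_{muscle}"] = synthesize_raw_emg(
            env, rng_car, cfg.noise_floor_mv, cfg.carrier_band)

    # ground-truth events on the mechanics clock, complete strides only
    hs_t = starts[starts < total_s]
    complete = hs_t[:-1] + durs[: hs_t.size - 1] <= total_s + 1e-9
    hs_idx = np.round(hs_t * cfg.sample_rate_mech).astype(int)
    to_t = starts + cfg.stance_fraction * durs
    to_idx = np.round(to_t * cfg.sample_rate_mech).astype(int)
    n_complete = int(complete.sum())
    hs_keep = hs_idx[: n_complete + 1]
    to_keep = to_idx[:n_complete]
    events = StrideEvents(hs_keep, to_keep, cfg.sample_rate_mech)

    gt = {
        "subject": {
            "amp_scale": sp["amp_scale"],
            "cadence": sp["cadence"],
            "adaptation": {m: a.model_dump() for m, a in sp["adaptation"].items()},
        },
        "condition": condition,
        "adaptation_end_factor": {
            m: float(
                _condition_amp_factors(
                    cfg, condition, m, sp["adaptation"][m], np.array([total_s])
                )[0]
            )
            for m in MUSCLES
        },
        "stride_starts_s": starts.tolist(),
        "stride_durations_s": durs.tolist(),
        "config": cfg.model_dump(mode="json"),
    }
    return TrialRecording(
        subject_id=f"S{subject_idx:02d}", condition=condition,
        channels=channels, events=events, ground_truth=gt,
    )


def generate_dataset(cfg: GeneratorConfig) -> list[TrialRecording]:
    """All subjects x all timeline conditions, in protocol order."""
    out = []
    for s in range(cfg.n_subjects):
        for entry in cfg.timeline:
            out.append(generate_trial(cfg, s, entry.condition))
    return out


# ---------------------------------------------------------------------------
# model-implied (noise-free) reference quantities
# ---------------------------------------------------------------------------


def nominal_percent_changes(cfg: GeneratorConfig) -> dict[str, float]:
    """Configured percent change per muscle at the end of powered practice."""
    p = cfg.powered_minutes()
    return {
        m: 100.0
        * cfg.adaptation[m].steady_state_change
        * (1.0 - np.exp(-p / cfg.adaptation[m].time_constant_min))
        for m in MUSCLES
    }


def nominal_decomposition(cfg: GeneratorConfig, controller_config=None) -> dict:
    """Noise-free, model-implied ankle decomposition at the end of practice.

    Runs the deterministic part of the device chain on the envelope
    template: the expected extracted envelope is the causal low-pass of the
    true envelope (the rectified-carrier scale cancels in calibration), the
    gain anchors the unpowered stride-peak to the current cap, and the
    resulting torque is decomposed against the moment/angle templates at
    nominal cadence.  This is the generator's configured contribution
    share, against which pipeline estimates are compared.
    """
    from .biomech import decompose_ankle  # deferred: biomech does not import us
    from .controller import ControllerConfig

    ctl = controller_config or ControllerConfig()
    T = 1.0 / cfg.cadence_mean
    fs = cfg.sample_rate_emg
    n_strides = 10
    t = np.arange(int(round(n_strides * T * fs))) / fs
    phase = np.mod(t / T, 1.0) * 100.0
    env = emg_envelope_template(cfg.burst_params["sol"], phase)
    lp = butter_sos("low", ctl.lp_cutoff, fs, ctl.filter_order)
    v = sps.sosfilt(lp, env)
    # steady-state stride (last full stride)
    i0 = int(round((n_strides - 1) * T * fs))
    grid_t = (n_strides - 1) * T + (CYCLE_GRID / 100.0) * T
    v_stride = np.interp(grid_t, t, v)
    ref_max = float(v_stride.max())
    gain = ctl.i_max_qaxis / ref_max
    thr = ctl.threshold_fraction * ref_max

    p_min = cfg.powered_minutes()
    f_end = adaptation_factor(p_min, cfg.adaptation["sol"])
    v_end = v_stride * f_end
    current = np.clip(gain * v_end, 0.0, ctl.i_max_qaxis)
    current[v_end < thr] = 0.0
    ratio = (
        ctl.transmission.ratio(cfg.discrepancy.angle_scale
                               * mechanics_template("ankle_angle", CYCLE_GRID)
                               + cfg.discrepancy.angle_offset)
        if ctl.transmission.tabulated else ctl.transmission.constant_nm_per_a
    )
    torque = ratio * current

    one = lambda curve, units: CycleEnsemble(
        curve[None, :], np.array([cfg.stance_fraction * 100.0]), np.array([T]), units)
    ang_df = mechanics_template("ankle_angle", CYCLE_GRID)
    pf_angle = one(-ang_df, "deg")                       # plantarflexion-positive
    exo_pf_angle = one(-(cfg.discrepancy.angle_scale * ang_df
                         + cfg.discrepancy.angle_offset), "deg")
    total_m = one(mechanics_template("ankle_moment", CYCLE_GRID), "Nm/kg")
    exo_tau = one(torque, "Nm")
    dec = decompose_ankle(total_m, exo_tau, cfg.body_mass, pf_angle,
                          exo_angle=exo_pf_angle)
    return {
        "gain_a_per_unit": gain,
        "adaptation_end_factor_sol": float(f_end),
        "peak_exo_torque_nm": float(torque.max()),
        "peak_exo_moment_nm_per_kg": float(dec.exo_moment.mean.max()),
        "peak_total_moment_nm_per_kg": float(dec.total_moment.mean.max()),
        "peak_exo_power_w_per_kg": float(dec.exo_power.mean.max()),
        "peak_total_power_w_per_kg": float(dec.total_power.mean.max()),
        "peak_power_share": dec.peak_power_share,
        "peak_moment_share": dec.peak_moment_share,
        "positive_work_share": dec.positive_work_share,
        "decomposition": dec,
    }
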