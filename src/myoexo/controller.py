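"""Proportional myoelectric controller chain.

The control signal is the linear envelope of the soleus surface EMG:
causal 2nd-order Butterworth high-pass at 50 Hz, full-wave rectification,
causal 2nd-order Butterworth low-pass at 8 Hz.  A subject-specific static
gain maps the envelope to motor q-axis current, capped at 7.6 A, with a
small deadband so the device is transparent during swing; current times a
transmission ratio (constant, or tabulated against the exoskeleton ankle
angle) gives a plantarflexion-only assistive torque.

All filters here are causal: the device runs in real time, so sample t of
every output depends only on inputs up to t.  Offline analysis elsewhere
may use zero-phase filtering; the controller never does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .signals import SampledSignal, StrideEvents, butter_sos, causal_filter


class TransmissionSpec(BaseModel):
    """Current-to-torque map: constant Nm/A gain or a ratio-vs-angle table.

    When tabulated, ``angles_deg``/``ratios_nm_per_a`` define ratio(angle) by
    linear interpolation; angles outside the table hull are clamped to the
    nearest edge.
    """

    constant_nm_per_a: Optional[float] = 2.2
    angles_deg: Optional[list[float]] = None
    ratios_nm_per_a: Optional[list[float]] = None

    @model_validator(mode="after")
    def _check(self) -> "TransmissionSpec":
        tab = self.angles_deg is not None or self.ratios_nm_per_a is not None
        if tab:
            if self.angles_deg is None or self.ratios_nm_per_a is None:
                raise ValueError("tabulated transmission needs both angles and ratios")
            if len(self.angles_deg) != len(self.ratios_nm_per_a) or len(self.angles_deg) < 2:
                raise ValueError("transmission table needs >=2 matched rows")
            if np.any(np.diff(self.angles_deg) <= 0):
                raise ValueError("transmission table angles must be increasing")
            if min(self.ratios_nm_per_a) < 0:
                raise ValueError("negative transmission ratio in table")
        elif self.constant_nm_per_a is None or self.constant_nm_per_a < 0:
            raise ValueError("constant transmission ratio must be >= 0")
        return self

    @property
    def tabulated(self) -> bool:
        return self.angles_deg is not None

    def ratio(self, exo_angle_deg: np.ndarray | float) -> np.ndarray:
        """Transmission ratio (Nm/A) at the given exoskeleton angle(s)."""
        if not self.tabulated:
            return np.broadcast_to(
                np.float64(self.constant_nm_per_a), np.shape(exo_angle_deg)
            ).copy() if np.ndim(exo_angle_deg) else np.float64(self.constant_nm_per_a)
        # np.interp clamps outside the hull by construction
        return np.interp(exo_angle_deg, self.angles_deg, self.ratios_nm_per_a)


class ControllerConfig(BaseModel):
    """All controller constants.

    i_line_to_line_equiv is informational only (the vendor's stated
    line-to-line equivalent of the 7.6 A q-axis cap); it never enters any
    computation.
    """

    hp_cutoff: float = 50.0          # Hz, high-pass on raw EMG
    lp_cutoff: float = 8.0           # Hz, low-pass on rectified EMG
    filter_order: int = 2
    i_max_qaxis: float = 7.6         # A, current saturation
    i_line_to_line_equiv: float = 20.0  # A, informational
    threshold_fraction: float = Field(0.05, ge=0.0, lt=1.0)
    transmission: TransmissionSpec = Field(default_factory=TransmissionSpec)
    torque_sign_plantarflexion_only: bool = True
    calibration_discard_s: float = 2.0  # filter start-up transient excluded from calibration

    @model_validator(mode="after")
    def _check(self) -> "ControllerConfig":
        if not 0 < self.lp_cutoff < self.hp_cutoff:
            raise ValueError("need 0 < lp_cutoff < hp_cutoff")
        if self.i_max_qaxis <= 0:
            raise ValueError("i_max_qaxis must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        return self


@dataclass
class CalibrationResult:
    """Subject-specific static gain and deadband threshold.

    gain maps envelope (mV) to q-axis current (A); threshold is in envelope
    units.  ``reference_max`` records the envelope maximum the gain was
    anchored to, ``method`` how it was taken (absolute max of the window or
    peak of the stride-averaged mean curve).
    """

    gain: float
    threshold: float
    reference_max: float
    method: str = "absolute_max"

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("gain must be positive")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


@dataclass
class ControllerOutput:
    """Envelope, commanded current and torque, all on the EMG clock."""

    envelope: SampledSignal
    current: SampledSignal
    torque: SampledSignal


def preprocess_emg(raw: SampledSignal, config: ControllerConfig) -> SampledSignal:
    """Linear envelope: causal HP -> full-wave rectify -> causal LP.

    Output is clipped at zero (the low-pass can undershoot slightly after
    sharp amplitude drops; negative activation is meaningless).
    """
    if raw.rate <= 2 * config.hp_cutoff:
        raise ValueError(
            f"sample rate {raw.rate} Hz too low for {config.hp_cutoff} Hz high-pass"
        )
    if np.any(~np.isfinite(raw.values)):
        raise ValueError("raw EMG contains NaN/inf")
    hp = butter_sos("high", config.hp_cutoff, raw.rate, config.filter_order)
    lp = butter_sos("low", config.lp_cutoff, raw.rate, config.filter_order)
    env = causal_filter(np.abs(causal_filter(raw.values, hp)), lp)
    return SampledSignal(raw.rate, np.clip(env, 0.0, None), raw.units)


def calibrate(
    envelope: SampledSignal,
    config: ControllerConfig,
    events: Optional[StrideEvents] = None,
) -> CalibrationResult:
    """Determine the static gain and threshold from an unpowered walking bout.

    The gain is chosen so the controlling current reaches the 7.6 A cap on
    the calibration window.  With stride ``events`` the envelope maximum is
    the peak of the stride-averaged mean curve (robust to single-stride
    excursions; individual strides then saturate at the cap); without
    events it is the absolute maximum of the window.  The first
    ``calibration_discard_s`` seconds are excluded to drop the filter
    start-up transient.
    """
    if envelope.duration < 10.0:
        raise ValueError("calibration window must cover >= 10 s of walking")
    discard = int(config.calibration_discard_s * envelope.rate)
    tail = envelope.values[discard:]
    if events is not None and events.n_strides >= 3:
        from .biomech import time_normalize  # local import to avoid a cycle

        ens = time_normalize(envelope, events)
        ref_max = float(ens.mean.max())
        method = "stride_mean_max"
    else:
        ref_max = float(tail.max())
        method = "absolute_max"
    if ref_max <= 0:
        raise ValueError("cannot calibrate on an all-zero envelope")
    return CalibrationResult(
        gain=config.i_max_qaxis / ref_max,
        threshold=config.threshold_fraction * ref_max,
        reference_max=ref_max,
        method=method,
    )


def command_current(
    envelope: SampledSignal, calibration: CalibrationResult, config: ControllerConfig
) -> SampledSignal:
    """Envelope -> q-axis current: deadband, static gain, saturation.

    Samples with envelope below the threshold command zero current, so the
    device is transparent during swing; above it, current = gain * envelope
    clipped to [0, i_max].
    """
    i = np.clip(calibration.gain * envelope.values, 0.0, config.i_max_qaxis)
    i[envelope.values < calibration.threshold] = 0.0
    return SampledSignal(envelope.rate, i, "A")


def current_to_torque(
    current: SampledSignal,
    exo_angle: Optional[SampledSignal],
    config: ControllerConfig,
) -> SampledSignal:
    """Current -> ankle torque through the transmission ratio.

    A tabulated transmission is evaluated at the exoskeleton ankle angle
    (resampled to the current clock if rates differ, clamped to the table
    hull); the plantarflexion-only flag clips torque at zero.
    """
    if config.transmission.tabulated:
        if exo_angle is None:
            raise ValueError("tabulated transmission requires the exoskeleton angle")
        ang = exo_angle.values
        if exo_angle.rate != current.rate:
            ang = np.interp(current.times, exo_angle.times, exo_angle.values)
        ratio = config.transmission.ratio(ang)
    else:
        ratio = config.transmission.constant_nm_per_a
    tau = ratio * current.values
    if config.torque_sign_plantarflexion_only:
        tau = np.clip(tau, 0.0, None)
    return SampledSignal(current.rate, tau, "Nm")


class MyoelectricController:
    """Convenience wrapper: calibrate once, then run the full chain.

    >>> ctl = MyoelectricController(ControllerConfig())
    >>> ctl.calibrate_from_raw(unpowered_sol)           # doctest: +SKIP
    >>> out = ctl.apply(powered_sol, exo_angle)         # doctest: +SKIP
    """

    def __init__(self, config: Optional[ControllerConfig] = None):
        self.config = config or ControllerConfig()
        self.calibration: Optional[CalibrationResult] = None

    def calibrate_from_raw(
        self, raw: SampledSignal, events: Optional[StrideEvents] = None
    ) -> CalibrationResult:
        self.calibration = calibrate(preprocess_emg(raw, self.config), self.config, events)
        return self.calibration

    def apply(
        self, raw: SampledSignal, exo_angle: Optional[SampledSignal] = None
    ) -> ControllerOutput:
        if self.calibration is None:
            raise RuntimeError("controller is not calibrated")
        env = preprocess_emg(raw, self.config)
        cur = command_current(env, self.calibration, self.config)
        tau = current_to_torque(cur, exo_angle, self.config)
        return ControllerOutput(envelope=env, current=cur, torque=tau)
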