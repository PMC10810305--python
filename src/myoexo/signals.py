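"""Core sampled-signal and gait-cycle containers.

These are the currencies the rest of the package trades in: uniformly
sampled channels (:class:`SampledSignal`), heel-strike/toe-off event trains
(:class:`StrideEvents`), and sets of time-normalized 101-point gait-cycle
curves (:class:`CycleEnsemble`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

#: Number of points on the gait-cycle grid, heel contact at 0%, inclusive of 100%.
CYCLE_POINTS = 101

#: The 0..100 %-cycle grid shared by every cycle curve in the package.
CYCLE_GRID = np.linspace(0.0, 100.0, CYCLE_POINTS)


@dataclass
class SampledSignal:
    """A uniformly sampled channel.

    Parameters
    ----------
    rate : float
        Sampling rate in Hz.
    values : ndarray
        Sample values; 1-D.
    units : str
        Physical units of ``values`` (e.g. ``"mV"``, ``"deg"``, ``"Nm/kg"``).
    """

    rate: float
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("SampledSignal values must be 1-D")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Signal span in seconds."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.rate

    def slice_time(self, t0: float, t1: float) -> "SampledSignal":
        """Return the sub-signal covering [t0, t1) seconds."""
        i0 = max(int(np.ceil(t0 * self.rate)), 0)
        i1 = min(int(np.ceil(t1 * self.rate)), self.n)
        return SampledSignal(self.rate, self.values[i0:i1], self.units)


@dataclass
class StrideEvents:
    """Heel-strike and toe-off sample indices on one channel's clock.

    Strides run heel strike to next ipsilateral heel strike; exactly one
    toe-off falls between consecutive heel strikes.
    """

    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=int)
        self.toe_offs = np.asarray(self.toe_offs, dtype=int)
        if np.any(np.diff(self.heel_strikes) <= 0) or np.any(np.diff(self.toe_offs) <= 0):
            raise ValueError("event indices must be strictly increasing")
        # one toe-off strictly inside every complete stride
        for i in range(self.n_strides):
            lo, hi = self.heel_strikes[i], self.heel_strikes[i + 1]
            inside = (self.toe_offs > lo) & (self.toe_offs < hi)
            if inside.sum() != 1:
                raise ValueError(
                    f"stride {i} must contain exactly one toe-off, found {inside.sum()}"
                )

    @property
    def n_strides(self) -> int:
        """Number of complete heel-strike-to-heel-strike strides."""
        return max(self.heel_strikes.size - 1, 0)

    @property
    def heel_strike_times(self) -> np.ndarray:
        return self.heel_strikes / self.rate

    @property
    def toe_off_times(self) -> np.ndarray:
        return self.toe_offs / self.rate

    def stride_spans(self) -> list[tuple[float, float, float]]:
        """(start, toe_off, end) times in seconds for each complete stride."""
        spans = []
        for i in range(self.n_strides):
            t0 = self.heel_strikes[i] / self.rate
            t1 = self.heel_strikes[i + 1] / self.rate
            to = self.toe_offs[(self.toe_offs > self.heel_strikes[i])
                               & (self.toe_offs < self.heel_strikes[i + 1])][0] / self.rate
            spans.append((t0, to, t1))
        return spans

    def subset(self, start: int, stop: int) -> "StrideEvents":
        """Events restricted to strides [start, stop)."""
        hs = self.heel_strikes[start:stop + 1]
        to = self.toe_offs[(self.toe_offs > hs[0]) & (self.toe_offs < hs[-1])]
        return StrideEvents(hs, to, self.rate)


@dataclass
class CycleEnsemble:
    """A set of gait-cycle curves on the common 0-100% grid.

    ``curves`` has shape (n_strides, 101) with heel contact at column 0.
    ``stance_end`` gives the toe-off as %cycle per stride, ``durations``
    the stride time in seconds.
    """

    curves: np.ndarray
    stance_end: np.ndarray
    durations: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if self.curves.shape[1] != CYCLE_POINTS:
            raise ValueError(f"cycle curves must have {CYCLE_POINTS} points")
        self.stance_end = np.asarray(self.stance_end, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.stance_end.size != self.n_strides or self.durations.size != self.n_strides:
            raise ValueError("stance_end/durations must have one entry per stride")

    @property
    def n_strides(self) -> int:
        return self.curves.shape[0]

    @property
    def grid(self) -> np.ndarray:
        return CYCLE_GRID

    @property
    def mean(self) -> np.ndarray:
        return self.curves.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.curves.std(axis=0, ddof=1) if self.n_strides > 1 else np.zeros(CYCLE_POINTS)

    @property
    def mean_stance_end(self) -> float:
        return float(self.stance_end.mean())

    def scaled(self, factor: float) -> "CycleEnsemble":
        return CycleEnsemble(self.curves * factor, self.stance_end, self.durations, self.units)


# ---------------------------------------------------------------------------
# Butterworth design + causal filtering
# ---------------------------------------------------------------------------

def butter_sos(kind: str, cutoff: float, rate: float, order: int = 2) -> np.ndarray:
    """Second-order-section Butterworth design.

    kind is ``"high"`` or ``"low"``; cutoff in Hz must be below Nyquist.
    """
    if not 0 < cutoff < rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={rate / 2} Hz)")
    return sps.butter(order, cutoff, btype=kind, fs=rate, output="sos")


def causal_filter(values: np.ndarray, sos: np.ndarray) -> np.ndarray:
    """Forward-only (real-time realizable) filtering with zero initial state."""
    return sps.sosfilt(sos, values)


def zero_phase_filter(values: np.ndarray, sos: np.ndarray) -> np.ndarray:
    """Forward-backward filtering for offline analysis (no phase lag)."""
    return sps.sosfiltfilt(sos, values)
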