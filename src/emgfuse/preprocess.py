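"""Signal conditioning: EMG/IMU filtering and IMU upsampling to 200 Hz.

Filtering is zero-phase (forward-backward) by default; a causal variant is
available through ``FilterSpec``/function arguments since offline analysis is
the intended use but a streaming deployment would need causal filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

__all__ = ["FilterSpec", "filter_emg", "filter_imu", "upsample_imu", "SignalLengthError"]


class SignalLengthError(ValueError):
    """Input too short for the requested filter or interpolation."""


@dataclass(frozen=True)
class FilterSpec:
    """One filter stage of the conditioning cascade."""

    kind: str                    # highpass | lowpass | bandpass | notch
    order: int
    cutoffs_hz: tuple[float, ...]
    q: float = 30.0              # notch quality factor

    def __post_init__(self) -> None:
        if self.kind not in {"highpass", "lowpass", "bandpass", "notch"}:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, rate: float) -> np.ndarray:
        nyq = rate / 2.0
        if any(not 0 < c < nyq for c in self.cutoffs_hz):
            raise ValueError(f"cutoffs {self.cutoffs_hz} must lie strictly inside (0, {nyq})")
        if self.kind == "notch":
            b, a = signal.iirnotch(self.cutoffs_hz[0], self.q, fs=rate)
            return signal.tf2sos(b, a)
        wn = self.cutoffs_hz if len(self.cutoffs_hz) > 1 else self.cutoffs_hz[0]
        return signal.butter(self.order, wn, btype=self.kind, fs=rate, output="sos")


EMG_NOTCH = FilterSpec("notch", 2, (60.0,))
EMG_HIGHPASS = FilterSpec("highpass", 4, (20.0,))
IMU_BANDPASS = FilterSpec("bandpass", 4, (0.2, 15.0))


def _apply(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def _check_length(x: np.ndarray, order: int) -> None:
    if x.shape[-1] <= 3 * order:
        raise SignalLengthError(
            f"signal length {x.shape[-1]} too short for order-{order} filtering"
        )


def filter_emg(emg: np.ndarray, rate: float = 200.0, zero_phase: bool = True) -> np.ndarray:
    """Per channel: remove mean, 60 Hz notch, 4th-order Butterworth HP at 20 Hz."""
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    _check_length(emg, EMG_HIGHPASS.order)
    x = emg - emg.mean(axis=-1, keepdims=True)
    x = _apply(EMG_NOTCH.sos(rate), x, zero_phase)
    x = _apply(EMG_HIGHPASS.sos(rate), x, zero_phase)
    return x


def filter_imu(imu: np.ndarray, rate: float = 50.0, zero_phase: bool = True) -> np.ndarray:
    """Per axis 4th-order Butterworth band-pass 0.2-15 Hz."""
    imu = np.atleast_2d(np.asarray(imu, dtype=float))
    _check_length(imu, IMU_BANDPASS.order)
    return _apply(IMU_BANDPASS.sos(rate), imu, zero_phase)


def upsample_imu(
    imu: np.ndarray, rate_in: float = 50.0, rate_out: float = 200.0
) -> np.ndarray:
    """Cubic-spline interpolation of each axis onto the EMG sample grid.

    Values at the original sample instants are reproduced exactly; the output
    grid covers the same duration at ``rate_out``.
    """
    imu = np.atleast_2d(np.asarray(imu, dtype=float))
    m = imu.shape[-1]
    if m < 4:
        raise SignalLengthError("need at least 4 samples for cubic-spline upsampling")
    ratio = rate_out / rate_in
    t_in = np.arange(m) / rate_in
    n_out = int(round(m * ratio))
    t_out = np.arange(n_out) / rate_out
    t_out = t_out[t_out <= t_in[-1] + 1e-12]
    spline = CubicSpline(t_in, imu, axis=-1)
    return spline(t_out)
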