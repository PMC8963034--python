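"""Muscle-activity interval detection.

The detector conditions each EMG channel with the Teager-Kaiser energy
operator (TKEO), low-pass filters and rectifies it, averages across channels,
smooths the average with a forward sliding RMS window, and then applies a
peak-referenced double threshold: the onset threshold is 20% of the mean of
all local maxima exceeding 10% of the global maximum, and the offset
threshold is 60% of the onset threshold.  Recordings in which more than one
disjoint supra-threshold region survives are flagged ``ambiguous`` and all
candidate regions are returned for manual (or planted ground-truth)
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from emgfuse.preprocess import FilterSpec, SignalLengthError, _apply

__all__ = [
    "EnergyProfile",
    "ActiveSegment",
    "NoActivityError",
    "tkeo",
    "condition_channels",
    "average_channels",
    "rms_smooth",
    "detect_active_region",
    "apply_segment",
    "energy_profile",
]

RMS_WINDOW = 60
ONSET_PEAK_FRACTION = 0.20
PEAK_KEEP_FRACTION = 0.10
OFFSET_FRACTION = 0.60

TKEO_LOWPASS = FilterSpec("lowpass", 4, (50.0,))


class NoActivityError(ValueError):
    """The smoothed energy trace contains no detectable activity."""


@dataclass
class EnergyProfile:
    """Intermediate energy traces of the detector, kept for inspection."""

    psi_channels: np.ndarray      # (8, N) conditioned per-channel energy
    psi_avg: np.ndarray           # (N,)
    psi_rms: np.ndarray           # (N - W + 1,)
    rms_window: int = RMS_WINDOW


@dataclass
class ActiveSegment:
    """Detected [onset, offset) interval on the 200 Hz timeline."""

    onset_idx: int
    offset_idx: int
    status: str = "auto"                       # auto | manual | ambiguous
    onset_threshold: float = 0.0
    offset_threshold: float = 0.0
    candidates: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.onset_idx >= self.offset_idx:
            raise ValueError("onset_idx must precede offset_idx")

    @property
    def length(self) -> int:
        return self.offset_idx - self.onset_idx


def tkeo(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy: psi_i = x_i^2 - x_{i+1} * x_{i-1}; endpoints 0."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise SignalLengthError("TKEO needs at least 3 samples")
    psi = np.zeros_like(x)
    psi[..., 1:-1] = x[..., 1:-1] ** 2 - x[..., 2:] * x[..., :-2]
    return psi


def condition_channels(emg: np.ndarray, rate: float = 200.0, zero_phase: bool = True) -> np.ndarray:
    """Per channel: TKEO -> 4th-order Butterworth low-pass 50 Hz -> rectify."""
    psi = tkeo(np.atleast_2d(emg))
    psi = _apply(TKEO_LOWPASS.sos(rate), psi, zero_phase)
    return np.abs(psi)


def average_channels(psi_channels: np.ndarray) -> np.ndarray:
    psi_channels = np.atleast_2d(psi_channels)
    if psi_channels.shape[0] < 1 or psi_channels.size == 0:
        raise ValueError("need at least one channel")
    return psi_channels.mean(axis=0)


def rms_smooth(psi_avg: np.ndarray, window: int = RMS_WINDOW) -> np.ndarray:
    """Forward sliding RMS: value at i covers samples [i, i+W-1]; length N-W+1."""
    psi_avg = np.asarray(psi_avg, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = psi_avg.shape[-1]
    if n < window:
        raise SignalLengthError(f"need at least {window} samples, got {n}")
    sq = psi_avg**2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    mean_sq = (csum[window:] - csum[:-window]) / window
    return np.sqrt(np.maximum(mean_sq, 0.0))


def energy_profile(emg: np.ndarray, rate: float = 200.0, window: int = RMS_WINDOW) -> EnergyProfile:
    psi_ch = condition_channels(emg, rate=rate)
    psi_avg = average_channels(psi_ch)
    return EnergyProfile(psi_ch, psi_avg, rms_smooth(psi_avg, window), window)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices strictly greater than both neighbours; plateaus -> first index."""
    idx = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[j]:
                j += 1
            if j + 1 < n and x[j + 1] < x[j]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return np.array(idx, dtype=int)


def detect_active_region(psi_rms: np.ndarray) -> ActiveSegment:
    """Peak-referenced double-threshold detection on the smoothed energy trace.

    Hysteresis: a region opens at the first sample >= onset_threshold and
    closes at the last sample >= offset_threshold before the trace drops
    below the offset threshold.  A single region is ``auto``; several disjoint
    regions flag the trial ``ambiguous`` with the overall [first onset, last
    offset) span returned alongside every candidate.
    """
    psi_rms = np.asarray(psi_rms, dtype=float)
    gmax = psi_rms.max(initial=0.0)
    if psi_rms.size == 0 or gmax <= 0:
        raise NoActivityError("smoothed energy trace has no positive values")
    peaks = _local_maxima(psi_rms)
    kept = peaks[psi_rms[peaks] > PEAK_KEEP_FRACTION * gmax]
    if kept.size == 0:
        # monotone or single-plateau trace: fall back to the global maximum
        kept = np.array([int(np.argmax(psi_rms))])
    onset_thr = ONSET_PEAK_FRACTION * psi_rms[kept].mean()
    offset_thr = OFFSET_FRACTION * onset_thr

    regions: list[tuple[int, int]] = []
    active = False
    start = 0
    for i, v in enumerate(psi_rms):
        if not active and v >= onset_thr:
            active = True
            start = i
        elif active and v < offset_thr:
            regions.append((start, i))
            active = False
    if active:
        regions.append((start, len(psi_rms)))
    if not regions:
        raise NoActivityError("no region exceeds the onset threshold")

    status = "auto" if len(regions) == 1 else "ambiguous"
    onset = regions[0][0]
    offset = regions[-1][1]
    return ActiveSegment(
        onset_idx=onset,
        offset_idx=offset,
        status=status,
        onset_threshold=onset_thr,
        offset_threshold=offset_thr,
        candidates=regions,
    )


def apply_segment(
    seg: ActiveSegment, emg: np.ndarray, imu_upsampled: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trim both modalities to the identical [onset, offset) range at 200 Hz."""
    emg = np.atleast_2d(emg)
    imu_upsampled = np.atleast_2d(imu_upsampled)
    n = min(emg.shape[-1], imu_upsampled.shape[-1])
    if not (0 <= seg.onset_idx < seg.offset_idx <= n):
        raise ValueError(
            f"segment [{seg.onset_idx}, {seg.offset_idx}) out of bounds for length {n}"
        )
    return (
        emg[:, seg.onset_idx : seg.offset_idx],
        imu_upsampled[:, seg.onset_idx : seg.offset_idx],
    )
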