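"""Windowing and time-domain feature extraction with feature-level fusion.

EMG windows yield MAV, MAVS, WL, 4th-order AR coefficients and ZC per channel
(64 values over 8 channels); IMU windows yield MAV and WL per axis (12 values
over 3 accelerometer + 3 gyroscope axes); fusion concatenates EMG then IMU
into a 76-vector.

AR coefficients use the Burg method in the prediction convention
``x_t = a_1 x_{t-1} + ... + a_p x_{t-p} + e_t`` (matching
``statsmodels.regression.linear_model.burg``); Yule-Walker is available via
``method="yule_walker"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "FeatureMatrix",
    "SegmentTooShortError",
    "window_segment",
    "burg_ar",
    "emg_features",
    "emg_feature_matrix",
    "imu_features",
    "imu_feature_matrix",
    "fuse",
    "EMG_FEATURE_NAMES",
    "IMU_FEATURE_NAMES",
]

AR_ORDER = 4
_EMG_PER_CHANNEL = ["mav", "mavs", "wl", "ar1", "ar2", "ar3", "ar4", "zc"]
EMG_FEATURE_NAMES = [f"ch{c+1}_{f}" for c in range(8) for f in _EMG_PER_CHANNEL]
_IMU_AXES = ["ax", "ay", "az", "gx", "gy", "gz"]
IMU_FEATURE_NAMES = [f"{ax}_{f}" for ax in _IMU_AXES for f in ("mav", "wl")]


class SegmentTooShortError(ValueError):
    """Active segment shorter than one analysis window."""


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 250 ms windows with 50% overlap at 200 Hz."""

    length_ms: float = 250.0
    overlap_fraction: float = 0.5
    rate_hz: float = 200.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.window_samples < 2:
            raise ValueError("window must span at least 2 samples")

    @property
    def window_samples(self) -> int:
        return int(round(self.length_ms * self.rate_hz / 1000.0))

    @property
    def step_samples(self) -> int:
        return max(int(round(self.window_samples * (1 - self.overlap_fraction))), 1)

    def n_windows(self, length: int) -> int:
        if length < self.window_samples:
            return 0
        return (length - self.window_samples) // self.step_samples + 1


def window_segment(segment: np.ndarray, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Split a (C, L) segment into full overlapping windows, shape (n, C, w)."""
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    L = segment.shape[-1]
    w, s = spec.window_samples, spec.step_samples
    if L < w:
        raise SegmentTooShortError(f"segment length {L} < window {w}")
    n = spec.n_windows(L)
    starts = np.arange(n) * s
    return np.stack([segment[:, a : a + w] for a in starts], axis=0)


def burg_ar(x: np.ndarray, order: int = AR_ORDER, demean: bool = True) -> np.ndarray:
    """Vectorized Burg AR estimate over the last axis.

    Accepts any leading shape; returns coefficients of shape ``x.shape[:-1] +
    (order,)`` in the prediction convention.  Degenerate (constant) inputs get
    all-zero coefficients with a logged warning instead of an error.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= order:
        raise ValueError(f"need more than {order} samples, got {x.shape[-1]}")
    if demean:
        x = x - x.mean(axis=-1, keepdims=True)
    degenerate = np.ptp(x, axis=-1) == 0
    if np.any(degenerate):
        logger.warning("constant window(s) encountered; AR coefficients set to 0")
    f = x.copy()
    b = x.copy()
    a = np.zeros(x.shape[:-1] + (order,))
    for m in range(1, order + 1):
        # error arrays shrink by one sample per stage
        fseg = f[..., 1:]
        bseg = b[..., :-1]
        num = 2.0 * np.sum(fseg * bseg, axis=-1)
        den = np.sum(fseg**2 + bseg**2, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        prev = a[..., : m - 1].copy()
        a[..., : m - 1] = prev - k[..., None] * prev[..., ::-1]
        a[..., m - 1] = k
        k_exp = k[..., None]
        f_new = fseg - k_exp * bseg
        b_new = bseg - k_exp * fseg
        f, b = f_new, b_new
    a[degenerate] = 0.0
    return a


def _yule_walker_ar(x: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    from statsmodels.regression.linear_model import yule_walker

    x = np.asarray(x, dtype=float)
    flat = x.reshape(-1, x.shape[-1])
    out = np.zeros((flat.shape[0], order))
    for i, row in enumerate(flat):
        if np.ptp(row) == 0:
            continue
        rho, _ = yule_walker(row, order=order, method="mle")
        out[i] = rho
    return out.reshape(x.shape[:-1] + (order,))


def _mav(w: np.ndarray) -> np.ndarray:
    return np.mean(np.abs(w), axis=-1)


def _wl(w: np.ndarray) -> np.ndarray:
    return np.sum(np.abs(np.diff(w, axis=-1)), axis=-1)


def _zc(w: np.ndarray, deadband: float = 0.0) -> np.ndarray:
    """Sign changes whose amplitude step exceeds the deadband."""
    s = np.sign(w)
    change = (s[..., :-1] * s[..., 1:]) < 0
    if deadband > 0:
        change &= np.abs(np.diff(w, axis=-1)) > deadband
    return change.sum(axis=-1).astype(float)


def emg_features(
    window: np.ndarray,
    prev_mav: np.ndarray | None = None,
    zc_deadband: float = 0.0,
    ar_method: str = "burg",
) -> np.ndarray:
    """Length-64 vector for one (8, w) EMG window.

    ``prev_mav`` is the previous window's per-channel MAV within the same
    active segment; MAVS is 0 for the first window.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    return emg_feature_matrix(
        window[None, ...],
        prev_mav=prev_mav,
        zc_deadband=zc_deadband,
        ar_method=ar_method,
        standalone=True,
    )[0]


def emg_feature_matrix(
    windows: np.ndarray,
    prev_mav: np.ndarray | None = None,
    zc_deadband: float = 0.0,
    ar_method: str = "burg",
    standalone: bool = False,
) -> np.ndarray:
    """(n, 8, w) windows of one active segment -> (n, 64) feature rows.

    MAVS of row i is MAV_i - MAV_{i-1} (0 for the first row unless
    ``prev_mav`` is given); when ``standalone`` the rows are treated as
    independent single-window calls rather than a contiguous segment.
    """
    windows = np.asarray(windows, dtype=float)
    n, c, _ = windows.shape
    mav = _mav(windows)                       # (n, c)
    if standalone:
        if prev_mav is None:
            mavs = np.zeros_like(mav)
        else:
            mavs = mav - np.asarray(prev_mav)
    else:
        mavs = np.zeros_like(mav)
        mavs[1:] = mav[1:] - mav[:-1]
        if prev_mav is not None:
            mavs[0] = mav[0] - np.asarray(prev_mav)
    wl = _wl(windows)
    if ar_method == "burg":
        ar = burg_ar(windows, AR_ORDER)
    elif ar_method == "yule_walker":
        ar = _yule_walker_ar(windows, AR_ORDER)
    else:
        raise ValueError(f"unknown AR method {ar_method!r}")
    zc = _zc(windows, zc_deadband)
    per_channel = np.concatenate(
        [mav[..., None], mavs[..., None], wl[..., None], ar, zc[..., None]], axis=-1
    )  # (n, c, 8)
    return per_channel.reshape(n, c * 8)


def imu_features(window: np.ndarray) -> np.ndarray:
    """Length-12 vector (MAV and WL per axis) for one (6, w) IMU window."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    return imu_feature_matrix(window[None, ...])[0]


def imu_feature_matrix(windows: np.ndarray) -> np.ndarray:
    windows = np.asarray(windows, dtype=float)
    n, c, _ = windows.shape
    mav = _mav(windows)
    wl = _wl(windows)
    per_axis = np.stack([mav, wl], axis=-1)   # (n, c, 2)
    return per_axis.reshape(n, c * 2)


def fuse(emg_vec: np.ndarray, imu_vec: np.ndarray) -> np.ndarray:
    """Feature-level fusion: EMG block first, IMU block second."""
    emg_vec = np.asarray(emg_vec, dtype=float)
    imu_vec = np.asarray(imu_vec, dtype=float)
    if emg_vec.ndim != imu_vec.ndim:
        raise ValueError("emg and imu blocks must have the same rank")
    if emg_vec.ndim == 2 and imu_vec.shape[1] and emg_vec.shape[0] != imu_vec.shape[0]:
        raise ValueError(
            f"window counts differ: {emg_vec.shape[0]} EMG vs {imu_vec.shape[0]} IMU"
        )
    return np.concatenate([emg_vec, imu_vec], axis=-1)


@dataclass
class FeatureMatrix:
    """Windows x features table with per-row labels and provenance."""

    values: np.ndarray                 # (n, d)
    labels: np.ndarray                 # gesture ids, (n,)
    subjects: np.ndarray               # (n,)
    positions: np.ndarray              # (n,)
    repetitions: np.ndarray            # (n,)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.values.shape[0]
        for name in ("labels", "subjects", "positions", "repetitions"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != {n} rows")
        if self.feature_names and len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match the feature dimension")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            self.values[:, idx], self.labels, self.subjects,
            self.positions, self.repetitions, list(names),
        )

    def mask_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[mask], self.labels[mask], self.subjects[mask],
            self.positions[mask], self.repetitions[mask], self.feature_names,
        )

    @staticmethod
    def concatenate(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        names = parts[0].feature_names
        for p in parts:
            if p.feature_names != names:
                raise ValueError("feature_names differ across parts")
        return FeatureMatrix(
            np.vstack([p.values for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.subjects for p in parts]),
            np.concatenate([p.positions for p in parts]),
            np.concatenate([p.repetitions for p in parts]),
            names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names or None)
        df.insert(0, "repetition", self.repetitions)
        df.insert(0, "position", self.positions)
        df.insert(0, "gesture", self.labels)
        df.insert(0, "subject", self.subjects)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = ["subject", "gesture", "position", "repetition"]
        names = [c for c in df.columns if c not in meta]
        return FeatureMatrix(
            df[names].to_numpy(float),
            df["gesture"].to_numpy(int),
            df["subject"].to_numpy(int),
            df["position"].to_numpy(int),
            df["repetition"].to_numpy(int),
            names,
        )
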