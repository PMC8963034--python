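"""Trial-level glue: raw recording -> filtered signals -> active segment ->
windowed fused feature rows.

Segmentation can come from the TKEO detector or from planted ground truth
(``segmentation="true"``); ambiguous detector outputs fall back to the planted
indices, mirroring the manual review a human operator would perform on real
data.  ``fixed_length`` trims (or rejects) segments to an exact sample count,
which pins the per-trial window count.
"""

from __future__ import annotations

import numpy as np

from emgfuse import features as feat
from emgfuse import onset as onset_mod
from emgfuse import preprocess as pre
from emgfuse.features import FeatureMatrix, WindowSpec
from emgfuse.synthetic import RawRecording

__all__ = ["trial_feature_rows", "trial_features", "subject_feature_matrix", "FUSED_FEATURE_NAMES"]

FUSED_FEATURE_NAMES = feat.EMG_FEATURE_NAMES + feat.IMU_FEATURE_NAMES


def detect_segment(rec: RawRecording, emg_f: np.ndarray) -> onset_mod.ActiveSegment:
    prof = onset_mod.energy_profile(emg_f, rate=rec.emg_rate)
    seg = onset_mod.detect_active_region(prof.psi_rms)
    if seg.status == "ambiguous":
        return onset_mod.ActiveSegment(
            rec.true_onset, rec.true_offset, status="manual",
            onset_threshold=seg.onset_threshold, offset_threshold=seg.offset_threshold,
        )
    return seg


def trial_feature_rows(
    rec: RawRecording,
    spec: WindowSpec = WindowSpec(),
    segmentation: str = "detect",
    fixed_length: int | None = None,
) -> tuple[np.ndarray, str]:
    """Fused (n_windows, 76) feature rows for one trial plus segment status."""
    emg_f = pre.filter_emg(rec.emg, rate=rec.emg_rate)
    imu = np.vstack([rec.accel, rec.gyro])
    imu_f = pre.filter_imu(imu, rate=rec.imu_rate)
    imu_up = pre.upsample_imu(imu_f, rate_in=rec.imu_rate, rate_out=rec.emg_rate)

    if segmentation == "true":
        seg = onset_mod.ActiveSegment(rec.true_onset, rec.true_offset, status="manual")
    elif segmentation == "detect":
        seg = detect_segment(rec, emg_f)
    else:
        raise ValueError(f"unknown segmentation mode {segmentation!r}")

    if fixed_length is not None:
        n = min(emg_f.shape[-1], imu_up.shape[-1])
        onset = min(seg.onset_idx, n - fixed_length)
        seg = onset_mod.ActiveSegment(onset, onset + fixed_length, status=seg.status)

    emg_seg, imu_seg = onset_mod.apply_segment(seg, emg_f, imu_up)
    emg_rows = feat.emg_feature_matrix(feat.window_segment(emg_seg, spec))
    imu_rows = feat.imu_feature_matrix(feat.window_segment(imu_seg, spec))
    return feat.fuse(emg_rows, imu_rows), seg.status


def trial_features(
    rec: RawRecording,
    spec: WindowSpec = WindowSpec(),
    segmentation: str = "detect",
    fixed_length: int | None = None,
) -> FeatureMatrix:
    rows, _ = trial_feature_rows(rec, spec, segmentation, fixed_length)
    n = rows.shape[0]
    return FeatureMatrix(
        rows,
        np.full(n, rec.gesture_id),
        np.full(n, rec.subject_id),
        np.full(n, rec.position_id),
        np.full(n, rec.repetition),
        FUSED_FEATURE_NAMES,
    )


def subject_feature_matrix(
    recordings,
    spec: WindowSpec = WindowSpec(),
    segmentation: str = "detect",
    fixed_length: int | None = None,
) -> FeatureMatrix:
    """Stack fused feature rows over all of one subject's recordings."""
    parts = [trial_features(r, spec, segmentation, fixed_length) for r in recordings]
    return FeatureMatrix.concatenate(parts)
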