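"""Normalization, subject-wise cross-validation and metrics.

The normalization chain is fitted on training-fold data only and applied
unchanged to test subjects: Z-normalization per feature, scaling to +-1,
then PCA (via SVD) keeping the smallest number of components whose
cumulative explained variance reaches 95%.

``run_experiment`` orchestrates the three user-independent methods over two
sensor modalities: per fold iteration it fits normalization and models on the
training folds, then runs each test subject through the method-specific
calibrate/test protocol (adaptive LS-SVM: two repetitions per gesture;
bilinear: one repetition of the calibration gesture; classic MLP: none).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from emgfuse import bilinear as bl
from emgfuse import lssvm
from emgfuse import mlp as mlp_mod
from emgfuse.features import EMG_FEATURE_NAMES, FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationState",
    "FoldAssignment",
    "ResultTable",
    "fit_normalization",
    "apply_normalization",
    "make_folds",
    "compute_metrics",
    "run_experiment",
]

EMG_DIM = len(EMG_FEATURE_NAMES)
METHODS = ("adaptive-lssvm", "bilinear", "classic-mlp")
MODALITIES = ("emg", "emg+imu")


# ---------------------------------------------------------------------------
# normalization / reduction
# ---------------------------------------------------------------------------

@dataclass
class NormalizationState:
    """Z-normalization -> +-1 scaling -> PCA at >= 95% retained variance."""

    mean: np.ndarray
    sd: np.ndarray
    keep: np.ndarray               # boolean mask of non-degenerate features
    post_z_absmax: np.ndarray      # per-feature max |z| used for +-1 scaling
    components: np.ndarray         # (n_components, d_kept) PCA basis rows
    pca_mean: np.ndarray
    explained_variance_ratio: np.ndarray
    variance_target: float = 0.95

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_normalization(
    X: np.ndarray, variance_target: float = 0.95
) -> NormalizationState:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty training matrix")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        logger.warning("dropping %d zero-variance feature(s)", int(np.sum(~keep)))
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    absmax = np.max(np.abs(Z), axis=0)
    absmax[absmax == 0] = 1.0
    S = Z / absmax

    pca_mean = S.mean(axis=0)
    _, svals, vt = np.linalg.svd(S - pca_mean, full_matrices=False)
    var = svals**2
    ratio = var / var.sum()
    cum = np.cumsum(ratio)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(ratio))
    return NormalizationState(
        mean=mean, sd=sd, keep=keep, post_z_absmax=absmax,
        components=vt[:k], pca_mean=pca_mean,
        explained_variance_ratio=ratio[:k], variance_target=variance_target,
    )


def apply_normalization(state: NormalizationState, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = (X[:, state.keep] - state.mean[state.keep]) / state.sd[state.keep]
    S = Z / state.post_z_absmax
    return (S - state.pca_mean) @ state.components.T


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    fold_of: dict                   # subject_id -> fold index (0-based)
    k: int
    seed: int

    def subjects_in(self, fold: int) -> list:
        return sorted(s for s, f in self.fold_of.items() if f == fold)

    @property
    def fold_sizes(self) -> list[int]:
        return [len(self.subjects_in(f)) for f in range(self.k)]


def make_folds(subject_ids, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Seeded subject-wise partition into k folds with sizes differing by <= 1."""
    subject_ids = list(subject_ids)
    if k > len(subject_ids):
        raise ValueError(f"k={k} exceeds the {len(subject_ids)} subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subject_ids))
    fold_of = {}
    for pos, idx in enumerate(order):
        fold_of[subject_ids[idx]] = pos % k
    return FoldAssignment(fold_of, k, seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(confusion: np.ndarray) -> dict:
    """Accuracy plus per-class precision/recall from a (true x predicted) count
    matrix; zero-denominator entries are NaN."""
    confusion = np.asarray(confusion)
    if np.any(confusion < 0):
        raise ValueError("confusion counts must be nonnegative")
    total = confusion.sum()
    tp = np.diag(confusion).astype(float)
    col = confusion.sum(axis=0).astype(float)
    row = confusion.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / col, np.nan)
        recall = np.where(row > 0, tp / row, np.nan)
    accuracy = float(tp.sum() / total) if total > 0 else np.nan
    return {"accuracy": accuracy, "precision": precision, "recall": recall}


@dataclass
class ResultTable:
    """Per-(subject, method, modality) accuracies plus pooled confusions."""

    rows: list = field(default_factory=list)   # dicts: subject, method, modality, accuracy, n
    confusions: dict = field(default_factory=dict)  # (method, modality) -> (C, C) counts
    classes: np.ndarray | None = None
    n_components: dict = field(default_factory=dict)

    def add(self, subject, method, modality, y_true, y_pred) -> None:
        acc = float(np.mean(y_true == y_pred))
        self.rows.append(
            {"subject": subject, "method": method, "modality": modality,
             "accuracy": acc, "n": int(len(y_true))}
        )
        key = (method, modality)
        c = len(self.classes)
        conf = self.confusions.setdefault(key, np.zeros((c, c), dtype=int))
        cls_index = {c_: i for i, c_ in enumerate(self.classes)}
        for t, p in zip(y_true, y_pred):
            conf[cls_index[t], cls_index[p]] += 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> pd.DataFrame:
        df = self.to_frame()
        agg = df.groupby(["method", "modality"])["accuracy"].agg(
            ["mean", "std", "min", "max"]
        )
        return agg.reset_index()

    def accuracy(self, method: str, modality: str) -> float:
        df = self.to_frame()
        sel = df[(df.method == method) & (df.modality == modality)]
        return float(sel.accuracy.mean())


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

def _derive_seed(root: int, *parts: int) -> int:
    return int(np.random.SeedSequence([root, *parts]).generate_state(1)[0])


def _modality_slice(fm: FeatureMatrix, modality: str) -> FeatureMatrix:
    if modality == "emg+imu":
        return fm
    if modality == "emg":
        return FeatureMatrix(
            fm.values[:, :EMG_DIM], fm.labels, fm.subjects,
            fm.positions, fm.repetitions, fm.feature_names[:EMG_DIM],
        )
    raise ValueError(f"unknown modality {modality!r}")


def _eval_adaptive_lssvm(
    train_fms: dict, test_fms: dict, results: ResultTable, modality: str,
    root_seed: int, gamma: float, adapt_iterations: int,
) -> None:
    state = fit_normalization(np.vstack([fm.values for fm in train_fms.values()]))
    priors = [
        lssvm.train_lssvm(
            apply_normalization(state, fm.values), fm.labels, gamma=gamma, subject_id=sid
        )
        for sid, fm in train_fms.items()
    ]
    results.n_components[("adaptive-lssvm", modality)] = state.n_components
    for sid, fm in test_fms.items():
        cal, test = lssvm.split_cal_test(fm, n_cal_reps=2, seed=_derive_seed(root_seed, 11, sid))
        Xc = apply_normalization(state, cal.values)
        Xt = apply_normalization(state, test.values)
        adapted = lssvm.adapt(priors, Xc, cal.labels, gamma=gamma, iterations=adapt_iterations)
        y_pred = lssvm.predict(adapted, Xt)
        results.add(sid, "adaptive-lssvm", modality, test.labels, y_pred)


def _eval_bilinear(
    train_fms: dict, test_fms: dict, results: ResultTable, modality: str,
    root_seed: int, mlp_spec: mlp_mod.MLPSpec, cal_gesture: int = 1,
) -> None:
    # bilinear factorization always runs on the EMG block; the IMU block joins
    # at the content-fusion step in the emg+imu modality
    train_list = list(train_fms.values())
    emg_parts = [
        FeatureMatrix(fm.values[:, :EMG_DIM], fm.labels, fm.subjects,
                      fm.positions, fm.repetitions, fm.feature_names[:EMG_DIM])
        for fm in train_list
    ]
    stacked, subj_idx = bl.stack_training_features(emg_parts)
    model = bl.fit_bilinear(stacked, subj_idx)
    content = bl.extract_content(model)
    ref = train_list[0]
    labels, positions, reps = ref.labels, ref.positions, ref.repetitions

    if modality == "emg+imu":
        imu_stack = np.vstack([fm.values[:, EMG_DIM:] for fm in train_list])
        X_train = bl.fuse_content_imu(content, imu_stack, mode="train", subject_index=subj_idx)
    else:
        X_train = content
    mu, sd = X_train.mean(axis=0), X_train.std(axis=0)
    sd[sd == 0] = 1.0
    spec = mlp_mod.MLPSpec(**{**mlp_spec.__dict__, "seed": _derive_seed(root_seed, 21)})
    net = mlp_mod.train_bilinear_mlp((X_train - mu) / sd, labels, spec)

    for sid, fm in test_fms.items():
        rng = np.random.default_rng(_derive_seed(root_seed, 22, sid))
        is_cal_g = fm.labels == cal_gesture
        rep_pos = np.unique(
            np.stack([fm.repetitions[is_cal_g], fm.positions[is_cal_g]], axis=1), axis=0
        )
        rep, pos = rep_pos[rng.integers(len(rep_pos))]
        cal_mask = is_cal_g & (fm.repetitions == rep) & (fm.positions == pos)
        test_mask = ~cal_mask

        # training content rows for the same (gesture, repetition, position) cell
        tr_mask = (labels == cal_gesture) & (reps == rep) & (positions == pos)
        if not np.any(tr_mask):  # repetition counts may differ across folds
            tr_mask = labels == cal_gesture
        n_cal = int(np.sum(cal_mask))
        content_cal = content[tr_mask][:n_cal]
        Y_cal = fm.values[cal_mask][: content_cal.shape[0], :EMG_DIM]
        adapted = bl.adapt_style(model, Y_cal, content_cal)
        c_test = bl.project_content(adapted, fm.values[test_mask][:, :EMG_DIM])
        if modality == "emg+imu":
            X_test = bl.fuse_content_imu(c_test, fm.values[test_mask][:, EMG_DIM:], mode="test")
        else:
            X_test = c_test
        y_pred = mlp_mod.predict_labels(net, (X_test - mu) / sd)
        results.add(sid, "bilinear", modality, fm.labels[test_mask], y_pred)


def _eval_classic_mlp(
    train_fms: dict, test_fms: dict, results: ResultTable, modality: str,
    root_seed: int, mlp_spec: mlp_mod.MLPSpec,
) -> None:
    X_all = np.vstack([fm.values for fm in train_fms.values()])
    y_all = np.concatenate([fm.labels for fm in train_fms.values()])
    state = fit_normalization(X_all)
    results.n_components[("classic-mlp", modality)] = state.n_components
    spec = mlp_mod.MLPSpec(**{**mlp_spec.__dict__, "seed": _derive_seed(root_seed, 31)})
    net, scaler, _ = mlp_mod.train_classic_mlp(apply_normalization(state, X_all), y_all, spec)
    for sid, fm in test_fms.items():
        y_pred = mlp_mod.predict_and_round(net, scaler, apply_normalization(state, fm.values))
        results.add(sid, "classic-mlp", modality, fm.labels, y_pred)


def run_experiment(
    subject_features: dict,
    methods=METHODS,
    modalities=MODALITIES,
    k: int = 5,
    seed: int = 0,
    gamma: float = 1.0,
    adapt_iterations: int = 100,
    bilinear_mlp_spec: mlp_mod.MLPSpec | None = None,
    classic_mlp_spec: mlp_mod.MLPSpec | None = None,
    max_fold_iterations: int | None = None,
) -> ResultTable:
    """Subject-wise k-fold evaluation of the requested methods x modalities.

    ``subject_features`` maps subject_id -> fused FeatureMatrix (76 columns).
    ``max_fold_iterations`` caps the number of test folds evaluated (reduced
    runs for budgeted experiments); all randomness derives from ``seed``.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    for m in modalities:
        if m not in MODALITIES:
            raise ValueError(f"unknown modality {m!r}")
    bilinear_mlp_spec = bilinear_mlp_spec or mlp_mod.BILINEAR_MLP_SPEC
    classic_mlp_spec = classic_mlp_spec or mlp_mod.CLASSIC_MLP_SPEC

    subject_ids = sorted(subject_features)
    folds = make_folds(subject_ids, k=k, seed=_derive_seed(seed, 1))
    classes = np.unique(np.concatenate([fm.labels for fm in subject_features.values()]))
    results = ResultTable(classes=classes)

    n_folds = folds.k if max_fold_iterations is None else min(folds.k, max_fold_iterations)
    for fold in range(n_folds):
        test_ids = folds.subjects_in(fold)
        train_ids = [s for s in subject_ids if s not in test_ids]
        if not test_ids or not train_ids:
            raise ValueError("fold assignment produced an empty train or test side")
        for modality in modalities:
            train_fms = {s: _modality_slice(subject_features[s], modality) for s in train_ids}
            test_fms = {s: _modality_slice(subject_features[s], modality) for s in test_ids}
            if "adaptive-lssvm" in methods:
                _eval_adaptive_lssvm(
                    train_fms, test_fms, results, modality,
                    _derive_seed(seed, 2, fold), gamma, adapt_iterations,
                )
            if "bilinear" in methods:
                _eval_bilinear(
                    train_fms, test_fms, results, modality,
                    _derive_seed(seed, 3, fold), bilinear_mlp_spec,
                )
            if "classic-mlp" in methods:
                _eval_classic_mlp(
                    train_fms, test_fms, results, modality,
                    _derive_seed(seed, 4, fold), classic_mlp_spec,
                )
    return results
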