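"""Symmetric bilinear style/content factorization of multi-subject features.

Observations are arranged as a (subjects, samples, channels) tensor where the
"channel" axis k runs over the feature dimensions; every scalar observation is
modelled as ``y[s, t, k] = z_s^T W_k x_t`` with per-subject style vectors
``z`` (dim I), per-motion-sample content vectors ``x`` (dim J, shared across
subjects) and per-channel weight matrices ``W_k``.  Fitting uses alternating
least squares: each of the three blocks (styles, contents, weights) is solved
exactly in turn, so the residual is monotonically nonincreasing.  The model
is identified only up to an invertible gauge transform ``(z, x, W) -> (A z,
B x, A^{-T} W B^{-1})``; recovery checks must therefore compare subspaces,
not coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from emgfuse.features import FeatureMatrix

__all__ = [
    "BilinearModel",
    "ContentMatrix",
    "DegenerateFitError",
    "stack_training_features",
    "fit_bilinear",
    "extract_content",
    "adapt_style",
    "project_content",
    "fuse_content_imu",
]


class DegenerateFitError(ValueError):
    """Data rank too low for the requested (I, J)."""


@dataclass
class BilinearModel:
    weights: np.ndarray                 # (K, I, J)
    styles: np.ndarray                  # (S, I)
    contents: np.ndarray                # (T, J)
    I: int = 2
    J: int = 3
    fit_residual: float = np.nan
    residual_history: list[float] = field(default_factory=list)
    new_style: np.ndarray | None = None  # z of an adapted (held-out) subject

    def reconstruct(self, styles: np.ndarray | None = None, contents: np.ndarray | None = None) -> np.ndarray:
        Z = self.styles if styles is None else np.atleast_2d(styles)
        X = self.contents if contents is None else np.atleast_2d(contents)
        return np.einsum("si,kij,tj->stk", Z, self.weights, X)


@dataclass
class ContentMatrix:
    """Per-sample content vectors arranged as classifier-ready rows."""

    values: np.ndarray                 # (T, J)
    labels: np.ndarray
    positions: np.ndarray
    repetitions: np.ndarray


def stack_training_features(per_subject: list[FeatureMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Vertical concatenation with a subject index per row.

    For the tensor arrangement the per-subject matrices must share both the
    feature dimension and (for the bilinear fit) the number of rows.
    """
    if not per_subject:
        raise ValueError("no feature matrices supplied")
    d = per_subject[0].n_features
    for fm in per_subject:
        if fm.n_features != d:
            raise ValueError("feature dimensions differ across subjects")
    stacked = np.vstack([fm.values for fm in per_subject])
    subj = np.concatenate([np.full(fm.n_rows, fm.subjects[0]) for fm in per_subject])
    return stacked, subj


def _to_tensor(stacked: np.ndarray, subject_index: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    subjects = np.unique(subject_index)
    counts = {s: int(np.sum(subject_index == s)) for s in subjects}
    t = counts[subjects[0]]
    if any(c != t for c in counts.values()):
        raise ValueError("subjects must contribute equal, aligned sample counts")
    K = stacked.shape[1]
    Y = np.empty((len(subjects), t, K))
    for i, s in enumerate(subjects):
        Y[i] = stacked[subject_index == s]
    return Y, subjects


def fit_bilinear(
    stacked: np.ndarray,
    subject_index: np.ndarray,
    I: int = 2,
    J: int = 3,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BilinearModel:
    """Alternating-least-squares fit of the (S, T, K) observation tensor.

    Initialization: content from the top-J right singular vectors of the
    stacked matrix, styles and weights from exact LS updates — deterministic.
    """
    Y, _ = _to_tensor(np.asarray(stacked, dtype=float), np.asarray(subject_index))
    S, T, K = Y.shape
    if S < 2:
        raise ValueError("need at least 2 subjects to separate style from content")
    flat = Y.reshape(S * T, K)
    rank = np.linalg.matrix_rank(flat)
    if rank < min(I, J):
        raise DegenerateFitError(
            f"data rank {rank} below requested factors (I={I}, J={J}); reduce I/J"
        )

    # init: content = top-J right-singular directions of the (S*T, K) stack,
    # projected back per sample; style starts at ones
    _, _, vt = np.linalg.svd(stacked - stacked.mean(0), full_matrices=False)
    X = stacked @ vt[:J].T
    X = X.reshape(S, T, J).mean(axis=0)        # (T, J) shared across subjects
    if np.linalg.matrix_rank(X) < J:
        X = X + 1e-6 * np.random.default_rng(0).normal(size=X.shape)
    Z = np.ones((S, I)) + 1e-3 * np.arange(S * I).reshape(S, I)
    W = np.zeros((K, I, J))

    total = float(np.sum(Y**2))
    history: list[float] = []
    prev = np.inf
    best = (np.inf, Z, W, X)
    for _ in range(max_iter):
        # --- W update: shared LS design over (s, t) pairs ---
        B = np.einsum("si,tj->stij", Z, X).reshape(S * T, I * J)
        Wf, *_ = np.linalg.lstsq(B, Y.reshape(S * T, K), rcond=None)
        W = Wf.T.reshape(K, I, J)
        # --- Z update: per subject ---
        G = np.einsum("kij,tj->tki", W, X).reshape(T * K, I)
        GtG = G.T @ G
        Z = np.linalg.lstsq(GtG, G.T @ Y.transpose(0, 1, 2).reshape(S, T * K).T, rcond=None)[0].T
        # --- X update: per sample ---
        H = np.einsum("si,kij->skj", Z, W).reshape(S * K, J)
        HtH = H.T @ H
        Yt = Y.transpose(1, 0, 2).reshape(T, S * K)
        X = np.linalg.lstsq(HtH, H.T @ Yt.T, rcond=None)[0].T

        resid = float(np.sum((Y - np.einsum("si,kij,tj->stk", Z, W, X)) ** 2))
        rel = resid / max(total, 1e-300)
        if rel > prev:
            # numerical floor reached: each block update is an exact LS solve,
            # so a true increase is impossible; keep the best iterate
            break
        history.append(rel)
        if rel < best[0]:
            best = (rel, Z.copy(), W.copy(), X.copy())
        if prev - rel < tol:
            break
        prev = rel

    _, Z, W, X = best
    return BilinearModel(
        weights=W, styles=Z, contents=X, I=I, J=J,
        fit_residual=best[0] if history else np.nan,
        residual_history=history,
    )


def extract_content(model: BilinearModel) -> np.ndarray:
    """Per-sample content vectors (T, J) as classifier-ready rows."""
    if model.contents is None:
        raise ValueError("model has not been fitted")
    return model.contents.copy()


def adapt_style(model: BilinearModel, Y_cal: np.ndarray, content_cal: np.ndarray) -> BilinearModel:
    """Least-squares style estimate for a new subject, weights frozen.

    ``Y_cal`` is (n_cal, K) observations of the calibration motion and
    ``content_cal`` the (n_cal, J) training content rows aligned to those
    samples.  Returns a copy of the model carrying ``new_style``.
    """
    Y_cal = np.atleast_2d(np.asarray(Y_cal, dtype=float))
    content_cal = np.atleast_2d(np.asarray(content_cal, dtype=float))
    if Y_cal.shape[0] == 0:
        raise ValueError("empty calibration set")
    if Y_cal.shape[0] != content_cal.shape[0]:
        raise ValueError("calibration observations and content rows misaligned")
    # y[t, k] = z^T (W_k x_t): design rows (W_k x_t)^T over all (t, k)
    G = np.einsum("kij,tj->tki", model.weights, content_cal)
    A = G.reshape(-1, model.I)
    b = Y_cal.reshape(-1)
    z_new, *_ = np.linalg.lstsq(A, b, rcond=None)
    return BilinearModel(
        weights=model.weights, styles=model.styles, contents=model.contents,
        I=model.I, J=model.J, fit_residual=model.fit_residual,
        residual_history=list(model.residual_history), new_style=z_new,
    )


def project_content(model: BilinearModel, Y_test: np.ndarray) -> np.ndarray:
    """Per-sample LS content vectors given the adapted style and frozen W."""
    if model.new_style is None:
        raise ValueError("model carries no adapted style; run adapt_style first")
    Y_test = np.atleast_2d(np.asarray(Y_test, dtype=float))
    A = np.einsum("i,kij->kj", model.new_style, model.weights)   # (K, J)
    if Y_test.shape[1] != A.shape[0]:
        raise ValueError(f"observation dim {Y_test.shape[1]} != channels {A.shape[0]}")
    X, *_ = np.linalg.lstsq(A, Y_test.T, rcond=None)
    return X.T


def fuse_content_imu(
    content: np.ndarray,
    imu_features: np.ndarray,
    mode: str = "test",
    subject_index: np.ndarray | None = None,
) -> np.ndarray:
    """Append IMU features to content rows.

    ``mode="train"`` averages the per-motion-sample IMU features across the
    training-fold subjects (requires ``subject_index`` aligned to the IMU
    rows); ``mode="test"`` appends the new subject's own IMU features.
    """
    content = np.atleast_2d(content)
    imu_features = np.atleast_2d(imu_features)
    if mode == "train":
        if subject_index is None:
            raise ValueError("train mode requires a subject index")
        subjects = np.unique(subject_index)
        t = content.shape[0]
        acc = np.zeros((t, imu_features.shape[1]))
        for s in subjects:
            block = imu_features[subject_index == s]
            if block.shape[0] != t:
                raise ValueError("IMU rows misaligned with content rows")
            acc += block
        imu_block = acc / len(subjects)
    elif mode == "test":
        if imu_features.shape[0] != content.shape[0]:
            raise ValueError("IMU rows misaligned with content rows")
        imu_block = imu_features
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.concatenate([content, imu_block], axis=1)
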