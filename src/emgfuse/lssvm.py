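"""Least-squares SVM predictive models and multi-model transfer adaptation.

Each subject gets a one-vs-all LS-SVM ensemble (7 binary machines).  The bias
is folded into the kernel (``K + 1``), and the ridge term is scaled by the
sample count so the decision function is invariant to duplicating the
training set.  For a new subject, a small calibration set (two repetitions of
each gesture) scores every pretrained model; adaptation then learns
per-class nonnegative weights ``beta`` over the prior decision functions by
projected subgradient descent on the closed-form leave-one-out hinge loss,
and retrains the LS-SVM on the calibration data with the beta-weighted prior
predictions as the transfer term:

    (K~ + (n/gamma) I) alpha_c = y_c - F_c beta_c
    f_c(x) = sum_i alpha_ci k~(x_i, x) + sum_k beta_ck f'_ck(x)

where ``F_c`` holds the prior models' class-c decision values on the
calibration points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from emgfuse.features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "LSSVMModel",
    "AdaptationResult",
    "train_lssvm",
    "predict",
    "decision_scores",
    "split_cal_test",
    "select_best_prior",
    "adapt",
]


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "rbf"              # rbf | linear
    bandwidth: float | None = None  # RBF length scale; None => median heuristic

    def __post_init__(self) -> None:
        if self.kind not in {"rbf", "linear"}:
            raise ValueError(f"unknown kernel {self.kind!r}")


def _median_bandwidth(X: np.ndarray, rng_cap: int = 500) -> float:
    n = X.shape[0]
    idx = np.linspace(0, n - 1, min(n, rng_cap)).astype(int)
    Xs = X[idx]
    d2 = np.sum((Xs[:, None, :] - Xs[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return float(np.sqrt(med / 2.0)) if med > 0 else 1.0


def _kernel(X: np.ndarray, Y: np.ndarray, spec: KernelSpec, bandwidth: float) -> np.ndarray:
    if spec.kind == "linear":
        return X @ Y.T
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * bandwidth**2))


@dataclass
class LSSVMModel:
    """One-vs-all LS-SVM ensemble over the 7 gesture classes."""

    X_train: np.ndarray            # (n, d)
    alphas: np.ndarray             # (n, n_classes) dual weights, bias folded in
    classes: np.ndarray            # sorted class ids
    kernel: KernelSpec
    bandwidth: float
    gamma: float
    subject_id: int | None = None

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if X.shape[1] != self.X_train.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension {self.X_train.shape[1]}"
            )
        Kt = _kernel(X, self.X_train, self.kernel, self.bandwidth) + 1.0
        return Kt @ self.alphas


class SingularSystemError(np.linalg.LinAlgError):
    pass


def train_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    gamma: float = 1.0,
    kernel: KernelSpec = KernelSpec(),
    subject_id: int | None = None,
) -> LSSVMModel:
    """Solve the one-vs-all LS-SVM dual systems for a labelled training set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes to train")
    n = X.shape[0]
    if n < classes.size:
        raise ValueError("fewer samples than classes")
    bandwidth = kernel.bandwidth if kernel.bandwidth else _median_bandwidth(X)
    Kt = _kernel(X, X, kernel, bandwidth) + 1.0
    A = Kt + (n / gamma) * np.eye(n)
    Y = np.where(y[:, None] == classes[None, :], 1.0, -1.0)
    try:
        alphas = np.linalg.solve(A, Y)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SingularSystemError(
            f"LS-SVM system singular; increase the ridge (gamma={gamma} too large?)"
        ) from exc
    return LSSVMModel(X, alphas, classes, kernel, bandwidth, gamma, subject_id)


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    if isinstance(model, AdaptationResult):
        base = model.adapted_model.decision(X)
        prior_scores = np.stack([p.decision(X) for p in model.priors], axis=-1)
        return base + np.einsum("nck,ck->nc", prior_scores, model.beta)
    return model.decision(X)


def predict(model, X: np.ndarray) -> np.ndarray:
    """Argmax of per-class scores; ties resolve to the lowest class id."""
    scores = decision_scores(model, X)
    classes = (
        model.adapted_model.classes if isinstance(model, AdaptationResult) else model.classes
    )
    return classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# calibration split and adaptation
# ---------------------------------------------------------------------------

def split_cal_test(
    subject_features: FeatureMatrix, n_cal_reps: int = 2, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Per gesture, route ``n_cal_reps`` random repetitions (all positions) to
    the calibration set; everything else is the test set."""
    rng = np.random.default_rng(seed)
    labels = subject_features.labels
    reps = subject_features.repetitions
    cal_mask = np.zeros(subject_features.n_rows, dtype=bool)
    for g in np.unique(labels):
        g_reps = np.unique(reps[labels == g])
        if g_reps.size < n_cal_reps + 1:
            raise ValueError(
                f"gesture {g}: need at least {n_cal_reps + 1} repetitions, have {g_reps.size}"
            )
        chosen = rng.choice(g_reps, size=n_cal_reps, replace=False)
        cal_mask |= (labels == g) & np.isin(reps, chosen)
    return subject_features.mask_rows(cal_mask), subject_features.mask_rows(~cal_mask)


def select_best_prior(
    priors: list[LSSVMModel], X_cal: np.ndarray, y_cal: np.ndarray
) -> list[tuple[int, float]]:
    """(prior index, calibration error rate) ranked ascending by error;
    ties break toward the lower prior index."""
    if not priors:
        raise ValueError("no prior models supplied")
    if len(y_cal) == 0:
        raise ValueError("empty calibration set")
    errors = [float(np.mean(predict(p, X_cal) != y_cal)) for p in priors]
    order = sorted(range(len(priors)), key=lambda i: (errors[i], i))
    return [(i, errors[i]) for i in order]


def _project_beta(beta: np.ndarray, radius: float = 1.0) -> np.ndarray:
    beta = np.maximum(beta, 0.0)
    norm = np.linalg.norm(beta)
    if norm > radius:
        beta = beta * (radius / norm)
    return beta


@dataclass
class AdaptationResult:
    """beta-weighted combination of prior models plus the retrained LS-SVM."""

    beta: np.ndarray               # (n_classes, n_priors), nonnegative, ||.|| <= 1
    adapted_model: LSSVMModel
    priors: list[LSSVMModel]
    cal_repetitions: dict = field(default_factory=dict)
    converged: bool = True
    loss_history: list[float] = field(default_factory=list)


def adapt(
    priors: list[LSSVMModel],
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    gamma: float = 1.0,
    kernel: KernelSpec = KernelSpec(),
    step_scale: float = 1.0,
    iterations: int = 300,
    radius: float = 1.0,
) -> AdaptationResult:
    """Learn per-class beta over prior decision functions and retrain on XCal.

    Minimizes the closed-form leave-one-out hinge loss of the transfer LS-SVM
    by projected subgradient descent (step ``step_scale / sqrt(t)``; projection
    onto the nonnegative L2 ball of the given radius).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal)
    n = X_cal.shape[0]
    classes = np.unique(y_cal)
    n_classes, n_priors = classes.size, len(priors)

    bandwidth = kernel.bandwidth if kernel.bandwidth else _median_bandwidth(X_cal)
    Kt = _kernel(X_cal, X_cal, kernel, bandwidth) + 1.0
    M = np.linalg.inv(Kt + (n / gamma) * np.eye(n))
    diag_m = np.diag(M)

    # prior decision values on the calibration set, per class: (n, C, P)
    F = np.stack([p.decision(X_cal) for p in priors], axis=-1)
    Ybin = np.where(y_cal[:, None] == classes[None, :], 1.0, -1.0)

    beta = np.zeros((n_classes, n_priors))
    best_beta = beta.copy()
    best_loss = np.inf
    history: list[float] = []
    for t in range(1, iterations + 1):
        loss = 0.0
        grad = np.zeros_like(beta)
        for c in range(n_classes):
            Fc = F[:, c, :]                       # (n, P)
            alpha = M @ (Ybin[:, c] - Fc @ beta[c])
            loo = Ybin[:, c] - alpha / diag_m     # LOO decision values
            margin = 1.0 - Ybin[:, c] * loo
            viol = margin > 0
            loss += float(np.sum(np.maximum(margin, 0.0)))
            if np.any(viol):
                # d loo_i / d beta = (M Fc)_i / M_ii ; d margin_i = -y_i * that
                dloo = (M @ Fc) / diag_m[:, None]
                grad[c] = -np.sum(Ybin[viol, c, None] * dloo[viol], axis=0)
        history.append(loss)
        if loss < best_loss:
            best_loss = loss
            best_beta = beta.copy()
        step = step_scale / np.sqrt(t)
        beta = _project_beta_rows(beta - step * grad, radius)

    converged = len(history) >= 2 and abs(history[-1] - best_loss) <= 1e-6 * max(best_loss, 1.0)
    if not converged:
        logger.warning("adaptation hit the iteration cap; returning the best iterate")
    beta = best_beta

    # final retrain on XCal with the transfer term
    alphas = M @ (Ybin - np.einsum("ncp,cp->nc", F, beta))
    adapted = LSSVMModel(X_cal, alphas, classes, kernel, bandwidth, gamma)
    return AdaptationResult(beta, adapted, list(priors), converged=converged, loss_history=history)


def _project_beta_rows(beta: np.ndarray, radius: float) -> np.ndarray:
    return np.vstack([_project_beta(row, radius) for row in beta])
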