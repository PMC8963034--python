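"""Multilayer-perceptron classifiers implemented on NumPy.

Two variants are used by the pipeline:

* the content-matrix network: input -> 50 (ReLU) -> dropout 20% -> batch norm
  -> 20 (ReLU) -> dropout 20% -> softmax over the 7 gestures, trained with
  Adam (lr 0.001, decay 1e-6) for 300 epochs on cross-entropy;
* the classic network: input -> 300 -> 200 -> 100 (logistic activations) ->
  scalar linear output, trained as regression on Z-standardized integer
  labels with plain SGD (lr 0.2) and an internal 80/20 train/validation
  split; predictions are unscaled, rounded to the nearest integer and clamped
  to the label range.

Everything is seeded: weight initialization (Glorot uniform), minibatch
shuffling and dropout masks all draw from one generator, so training is
bit-reproducible on a fixed thread count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MLPSpec",
    "LabelScaler",
    "MLPModel",
    "train_bilinear_mlp",
    "train_classic_mlp",
    "predict_proba",
    "predict_labels",
    "predict_and_round",
]


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MLPSpec:
    hidden_sizes: tuple[int, ...] = (50, 20)
    activation: str = "relu"            # relu | logistic
    output: str = "softmax"             # softmax | linear
    dropout_rate: float = 0.2
    batch_norm: bool = True
    optimizer: str = "adam"             # adam | sgd
    learning_rate: float = 0.001
    decay: float = 1e-6
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


BILINEAR_MLP_SPEC = MLPSpec()
# batch_size=1: classic per-pattern backpropagation — minibatch averaging at
# lr 0.2 is unstable for wide logistic layers (seed-dependent saturation)
CLASSIC_MLP_SPEC = MLPSpec(
    hidden_sizes=(300, 200, 100),
    activation="logistic",
    output="linear",
    dropout_rate=0.0,
    batch_norm=False,
    optimizer="sgd",
    learning_rate=0.2,
    decay=0.0,
    epochs=300,
    batch_size=1,
)


@dataclass
class LabelScaler:
    mean: float
    sd: float

    @staticmethod
    def fit(y: np.ndarray) -> "LabelScaler":
        y = np.asarray(y, dtype=float)
        sd = float(np.std(y))
        if sd <= 0:
            raise ValueError("labels have zero variance")
        return LabelScaler(float(np.mean(y)), sd)

    def scale(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.mean) / self.sd

    def unscale(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def _act(name: str, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (activation, derivative wrt pre-activation)."""
    if name == "relu":
        out = np.maximum(x, 0.0)
        return out, (x > 0).astype(x.dtype)
    if name == "logistic":
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        return out, out * (1.0 - out)
    raise ValueError(f"unknown activation {name!r}")


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, decay: float):
        self.lr, self.decay = lr, decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * self.t)
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= lr_t * mhat / (np.sqrt(vhat) + eps)


class _SGD:
    def __init__(self, params: list[np.ndarray], lr: float, decay: float):
        self.lr, self.decay = lr, decay
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * self.t)
        for p, g in zip(params, grads):
            p -= lr_t * g


@dataclass
class MLPModel:
    spec: MLPSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    bn_gamma: np.ndarray | None
    bn_beta: np.ndarray | None
    bn_mean: np.ndarray | None
    bn_var: np.ndarray | None
    classes: np.ndarray | None = None
    history: list[float] = field(default_factory=list)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Inference pass: dropout off, batch norm uses running statistics."""
        h = np.asarray(X, dtype=float)
        n_hidden = len(self.spec.hidden_sizes)
        for li in range(n_hidden):
            h, _ = _act(self.spec.activation, h @ self.weights[li] + self.biases[li])
            if self.spec.batch_norm and li == 0:
                h = (h - self.bn_mean) / np.sqrt(self.bn_var + 1e-5)
                h = h * self.bn_gamma + self.bn_beta
        z = h @ self.weights[-1] + self.biases[-1]
        if self.spec.output == "softmax":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return z


def _init_net(spec: MLPSpec, d_in: int, d_out: int, rng: np.random.Generator):
    dims = [d_in, *spec.hidden_sizes, d_out]
    weights, biases = [], []
    for a, b in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (a + b))
        weights.append(rng.uniform(-limit, limit, size=(a, b)))
        biases.append(np.zeros(b))
    return weights, biases


def _train(
    X: np.ndarray, T: np.ndarray, spec: MLPSpec, d_out: int
) -> MLPModel:
    """Minibatch training of the configured architecture.

    ``T`` is the target matrix: one-hot rows for softmax output, scalar
    column for linear output.
    """
    rng = np.random.default_rng(spec.seed)
    X = np.asarray(X, dtype=float)
    n, d_in = X.shape
    weights, biases = _init_net(spec, d_in, d_out, rng)
    n_hidden = len(spec.hidden_sizes)

    use_bn = spec.batch_norm
    bn_dim = spec.hidden_sizes[0] if use_bn else 0
    gamma = np.ones(bn_dim) if use_bn else None
    beta = np.zeros(bn_dim) if use_bn else None
    run_mean = np.zeros(bn_dim) if use_bn else None
    run_var = np.ones(bn_dim) if use_bn else None

    params = weights + biases + ([gamma, beta] if use_bn else [])
    opt_cls = _Adam if spec.optimizer == "adam" else _SGD
    opt = opt_cls(params, spec.learning_rate, spec.decay)

    keep = 1.0 - spec.dropout_rate
    bs = min(spec.batch_size, n)
    history: list[float] = []
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, tb = X[idx], T[idx]
            m = len(idx)

            # ---- forward ----
            h = xb
            caches = []
            bn_cache = None
            for li in range(n_hidden):
                z = h @ weights[li] + biases[li]
                a, da = _act(spec.activation, z)
                mask = None
                if keep < 1.0:
                    mask = (rng.random(a.shape) < keep) / keep
                    a = a * mask
                if use_bn and li == 0:
                    mu = a.mean(axis=0)
                    var = a.var(axis=0)
                    a_hat = (a - mu) / np.sqrt(var + 1e-5)
                    out = a_hat * gamma + beta
                    bn_cache = (a_hat, var, mu)
                    run_mean[:] = 0.9 * run_mean + 0.1 * mu
                    run_var[:] = 0.9 * run_var + 0.1 * var
                    caches.append((h, da, mask, out))
                    h = out
                else:
                    caches.append((h, da, mask, a))
                    h = a
            z_out = h @ weights[-1] + biases[-1]

            if spec.output == "softmax":
                z_out = z_out - z_out.max(axis=1, keepdims=True)
                e = np.exp(z_out)
                p = e / e.sum(axis=1, keepdims=True)
                loss = -np.mean(np.sum(tb * np.log(p + 1e-12), axis=1))
                delta = (p - tb) / m
            else:
                # half-MSE convention (delta = diff), matching classic
                # backpropagation implementations the lr 0.2 default assumes
                diff = z_out - tb
                loss = float(0.5 * np.mean(diff**2))
                delta = diff / m
            if not np.isfinite(loss):
                raise DivergenceError(
                    "loss became non-finite; lower the learning rate"
                )
            epoch_loss += loss * m

            # ---- backward ----
            gw = [None] * len(weights)
            gb = [None] * len(biases)
            h_last = caches[-1][3] if n_hidden else xb
            gw[-1] = h_last.T @ delta
            gb[-1] = delta.sum(axis=0)
            grad_h = delta @ weights[-1].T
            g_gamma = g_beta = None
            for li in range(n_hidden - 1, -1, -1):
                h_in, da, mask, _ = caches[li]
                if use_bn and li == 0:
                    a_hat, var, _ = bn_cache
                    g_gamma = np.sum(grad_h * a_hat, axis=0)
                    g_beta = np.sum(grad_h, axis=0)
                    dxhat = grad_h * gamma
                    inv = 1.0 / np.sqrt(var + 1e-5)
                    grad_h = inv * (
                        dxhat
                        - dxhat.mean(axis=0)
                        - a_hat * np.mean(dxhat * a_hat, axis=0)
                    )
                if mask is not None:
                    grad_h = grad_h * mask
                dz = grad_h * da
                gw[li] = h_in.T @ dz
                gb[li] = dz.sum(axis=0)
                if li > 0:
                    grad_h = dz @ weights[li].T

            grads = gw + gb + ([g_gamma, g_beta] if use_bn else [])
            opt.step(params, grads)
        history.append(epoch_loss / n)

    return MLPModel(
        spec=spec, weights=weights, biases=biases,
        bn_gamma=gamma, bn_beta=beta, bn_mean=run_mean, bn_var=run_var,
        history=history,
    )


def train_bilinear_mlp(X: np.ndarray, y: np.ndarray, spec: MLPSpec = BILINEAR_MLP_SPEC) -> MLPModel:
    """Softmax classifier over gesture labels for content-matrix inputs."""
    y = np.asarray(y)
    classes = np.unique(y)
    T = (y[:, None] == classes[None, :]).astype(float)
    model = _train(np.asarray(X, float), T, spec, d_out=classes.size)
    model.classes = classes
    return model


def train_classic_mlp(
    X: np.ndarray,
    y: np.ndarray,
    spec: MLPSpec = CLASSIC_MLP_SPEC,
    val_fraction: float = 0.2,
) -> tuple[MLPModel, LabelScaler, float]:
    """Regression on standardized integer labels with an 80/20 split.

    Returns (model, scaler, validation accuracy after rounding).  The split
    is pooled and seeded; the validation set only monitors generalization —
    no early stopping is applied.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    scaler = LabelScaler.fit(y)
    rng = np.random.default_rng(spec.seed)
    n = X.shape[0]
    order = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    T = scaler.scale(y)[:, None]
    model = _train(X[tr_idx], T[tr_idx], spec, d_out=1)
    if n_val:
        val_pred = predict_and_round(model, scaler, X[val_idx])
        val_acc = float(np.mean(val_pred == y[val_idx]))
    else:
        val_acc = np.nan
    return model, scaler, val_acc


def predict_proba(model: MLPModel, X: np.ndarray) -> np.ndarray:
    if model.spec.output != "softmax":
        raise ValueError("probabilities only defined for the softmax variant")
    return model.forward(X)


def predict_labels(model: MLPModel, X: np.ndarray) -> np.ndarray:
    p = predict_proba(model, X)
    return model.classes[np.argmax(p, axis=1)]


def predict_and_round(
    model: MLPModel,
    scaler: LabelScaler,
    X: np.ndarray,
    lo: int = 1,
    hi: int = 7,
) -> np.ndarray:
    """Unscale the linear output, round half away from zero, clamp to [lo, hi]."""
    raw = scaler.unscale(model.forward(X)[:, 0])
    rounded = np.sign(raw) * np.floor(np.abs(raw) + 0.5)
    return np.clip(rounded, lo, hi).astype(int)
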