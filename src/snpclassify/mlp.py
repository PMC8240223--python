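"""Multilayer-perceptron classifier over embedded genotypes.

The network is the classification head of the method: input layer of size k
(the embedding dimension), two relu hidden layers of 100 units, and a softmax
output over the c population classes.  Training minimises the squared error
between the softmax output and the one-hot labels,

    C_W(X', Y) = || phi_W(X') - Y ||_F^2,

by default (cross-entropy is available as an option).  Everything is plain
NumPy with explicit backpropagation: the perturbation step needs exact
gradients of C with respect to the *inputs*, so the same backward pass exposes
both weight gradients (for training) and input gradients (for IFGSM).  All
gradients are of the summed loss; per-sample terms are independent, so the
gradient of a batch is the row-stack of per-sample gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOSSES = ("mse_softmax", "cross_entropy")


@dataclass
class MLPModel:
    """Weights and biases of the relu/softmax network.

    ``weights[l]`` has shape (units_{l}, units_{l+1}); biases are kept
    explicit (the equivalent augmented-weight formulation folds them into W).

    ``input_mean``/``input_scale``, when set, define a *fixed* (non-trainable)
    standardisation of the input, ``(x - mean) / scale``, applied before the
    first layer.  The composite is still a deterministic map from raw embedded
    features, and all input gradients are taken with respect to the raw
    features (chain rule through the affine transform).  Without it, the large
    nearly-constant offsets of uncentered genotype embeddings make first-layer
    optimisation hopelessly ill-conditioned: any weight movement is amplified
    by the feature means and saturates the softmax, where the squared-error
    gradient vanishes.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_mean: np.ndarray | None = None
    input_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must have the same length")
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.ndim != 2 or b.shape != (w.shape[1],):
                raise ValueError(f"layer {i}: weight/bias shapes inconsistent")
            if i and self.weights[i - 1].shape[1] != w.shape[0]:
                raise ValueError(f"layer {i}: shape chain broken")
        k_in = self.weights[0].shape[0]
        if self.input_mean is not None and self.input_mean.shape != (k_in,):
            raise ValueError(f"input_mean must have shape ({k_in},)")
        if self.input_scale is not None:
            if self.input_scale.shape != (k_in,):
                raise ValueError(f"input_scale must have shape ({k_in},)")
            if np.any(self.input_scale <= 0):
                raise ValueError("input_scale entries must be positive")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0], *(w.shape[1] for w in self.weights))

    @property
    def n_classes(self) -> int:
        return self.weights[-1].shape[1]

    def copy(self) -> "MLPModel":
        return MLPModel(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            input_mean=None if self.input_mean is None else self.input_mean.copy(),
            input_scale=None if self.input_scale is None else self.input_scale.copy(),
        )

    def parameter_hash(self) -> str:
        """Stable digest of all parameters (frozen-weights checks)."""
        import hashlib

        h = hashlib.sha256()
        for w, b in zip(self.weights, self.biases):
            h.update(np.ascontiguousarray(w).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
        for t in (self.input_mean, self.input_scale):
            if t is not None:
                h.update(np.ascontiguousarray(t).tobytes())
        return h.hexdigest()


@dataclass
class TrainConfig:
    """Hyperparameters of the squared-error training loop.

    The optimizer, rate, epoch and batch settings are conventional defaults
    (Adam, 1e-3, 200 epochs, batches of 32) with early stopping once the
    epoch training loss stops improving for ``patience`` epochs.
    """

    loss: str = "mse_softmax"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    patience: int = 20

    def __post_init__(self) -> None:
        if self.loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}, got {self.loss!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def init_model(
    k_in: int,
    c: int,
    seed: int = 0,
    hidden: tuple[int, ...] = (100, 100),
    feature_mean: np.ndarray | None = None,
    feature_scale: np.ndarray | None = None,
) -> MLPModel:
    """He-initialised network with zero biases; deterministic given ``seed``.

    ``feature_mean``/``feature_scale`` install a fixed input standardisation
    in the model (see :class:`MLPModel`): pass the per-column mean and
    standard deviation of the embedded *training* matrix.  Columns with zero
    spread get scale 1.
    """
    if k_in < 1:
        raise ValueError("k_in must be >= 1")
    if c < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    sizes = (k_in, *hidden, c)
    weights = []
    biases = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
        biases.append(np.zeros(fan_out))
    mean = scale = None
    if feature_mean is not None:
        mean = np.asarray(feature_mean, dtype=float).copy()
    if feature_scale is not None:
        scale = np.asarray(feature_scale, dtype=float).copy()
        scale[scale <= 0] = 1.0
    return MLPModel(weights=weights, biases=biases, input_mean=mean, input_scale=scale)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_cache(model: MLPModel, X: np.ndarray):
    """Forward pass keeping activations and pre-activations for backprop."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"input has shape {X.shape}; expected (*, {model.layer_sizes[0]})"
        )
    a = X
    if model.input_mean is not None:
        a = a - model.input_mean
    if model.input_scale is not None:
        a = a / model.input_scale
    acts = [a]
    pre = []
    n_layers = len(model.weights)
    for l, (w, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ w + b
        pre.append(z)
        a = _softmax(z) if l == n_layers - 1 else np.maximum(z, 0.0)
        acts.append(a)
    return acts, pre


def forward(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Class-probability matrix phi_W(X'); rows lie on the simplex."""
    acts, _ = _forward_cache(model, X)
    return acts[-1]


def loss_value(
    model: MLPModel, X: np.ndarray, Y: np.ndarray, loss: str = "mse_softmax"
) -> float:
    """Summed loss over samples (the quantity the perturbation step minimises)."""
    P = forward(model, X)
    _check_labels(P, Y)
    if loss == "mse_softmax":
        return float(np.sum((P - Y) ** 2))
    if loss == "cross_entropy":
        return float(-np.sum(Y * np.log(np.clip(P, 1e-300, None))))
    raise ValueError(f"unknown loss {loss!r}")


def _check_labels(P: np.ndarray, Y: np.ndarray) -> None:
    if Y.shape != P.shape:
        raise ValueError(f"label matrix shape {Y.shape} != output shape {P.shape}")


def _output_delta(P: np.ndarray, Y: np.ndarray, loss: str) -> np.ndarray:
    """dC/dz at the softmax pre-activation, for the summed loss."""
    if loss == "mse_softmax":
        g = 2.0 * (P - Y)  # dC/dP
        return P * (g - np.sum(P * g, axis=1, keepdims=True))
    if loss == "cross_entropy":
        return P - Y
    raise ValueError(f"unknown loss {loss!r}")


def _backward(model: MLPModel, acts, pre, Y: np.ndarray, loss: str):
    """Gradients of the summed loss w.r.t. weights, biases, and the input."""
    P = acts[-1]
    _check_labels(P, Y)
    delta = _output_delta(P, Y, loss)
    d_weights = [None] * len(model.weights)
    d_biases = [None] * len(model.biases)
    for l in range(len(model.weights) - 1, -1, -1):
        d_weights[l] = acts[l].T @ delta
        d_biases[l] = delta.sum(axis=0)
        delta = delta @ model.weights[l].T
        if l > 0:
            delta = delta * (pre[l - 1] > 0)
    if model.input_scale is not None:
        delta = delta / model.input_scale  # chain rule through the fixed transform
    return d_weights, d_biases, delta  # final delta == dC/dX (raw input)


def input_gradient(
    model: MLPModel, X: np.ndarray, Y: np.ndarray, loss: str = "mse_softmax"
) -> np.ndarray:
    """Exact gradient of the summed loss with respect to each input row."""
    acts, pre = _forward_cache(model, X)
    _, _, dX = _backward(model, acts, pre, Y, loss)
    return dX


def train(
    model: MLPModel, X: np.ndarray, Y: np.ndarray, cfg: TrainConfig
) -> MLPModel:
    """Minibatch training of the configured loss; returns a new trained model.

    Deterministic given ``cfg.seed`` (batch shuffling is the only source of
    randomness).  The per-epoch mean training loss is recorded on the
    returned model as ``loss_curve_``.  ``epochs=0`` returns an untouched
    copy.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    out = model.copy()
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    params = out.weights + out.biases
    if cfg.optimizer == "adam":
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
        step = 0
    history: list[float] = []
    best = np.inf
    stall = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            acts, pre = _forward_cache(out, X[batch])
            dW, dB, _ = _backward(out, acts, pre, Y[batch], cfg.loss)
            grads = [g / len(batch) for g in dW + dB]
            if cfg.optimizer == "adam":
                step += 1
                for p, g, m_i, v_i in zip(params, grads, m_t, v_t):
                    m_i += (1 - beta1) * (g - m_i)
                    v_i += (1 - beta2) * (g * g - v_i)
                    mhat = m_i / (1 - beta1**step)
                    vhat = v_i / (1 - beta2**step)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps_adam)
            else:
                for p, g in zip(params, grads):
                    p -= cfg.learning_rate * g
        epoch_loss = loss_value(out, X, Y, cfg.loss) / n
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {_epoch}: {epoch_loss}; "
                "lower the learning rate"
            )
        history.append(epoch_loss)
        if epoch_loss < best - 1e-8:
            best = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    out.loss_curve_ = history
    return out


def evaluate(model: MLPModel, X: np.ndarray, y_true: np.ndarray) -> dict:
    """Accuracy and confusion matrix of argmax predictions.

    ``y_true`` holds class indices.  Ties at the argmax resolve to the lowest
    class index.  The confusion matrix has true classes as rows and predicted
    classes as columns; a row-normalised view is included for classes with at
    least one sample.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    P = forward(model, X)
    if y_true.shape[0] != P.shape[0]:
        raise ValueError("y_true length != number of samples")
    pred = np.argmax(P, axis=1)  # np.argmax returns the first (lowest) maximiser
    c = model.n_classes
    confusion = np.zeros((c, c), dtype=np.int64)
    np.add.at(confusion, (y_true, pred), 1)
    totals = confusion.sum(axis=1, keepdims=True)
    normalized = np.divide(
        confusion, totals, out=np.zeros((c, c)), where=totals > 0
    )
    accuracy = float(np.trace(confusion) / confusion.sum())
    return {
        "accuracy": accuracy,
        "confusion": confusion,
        "confusion_normalized": normalized,
        "predictions": pred,
    }
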