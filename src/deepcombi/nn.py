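"""Dense phenotype classifier: 64-64 ReLU network with a two-node softmax head.

Trained by Adam on a class-weighted cross-entropy loss with an L1+L2 mixed
penalty on the weight matrices (biases unpenalized), dropout after each hidden
layer, and learning-rate reduction on a validation-loss plateau. The network
is small enough that a plain numpy implementation is both fast and fully
transparent, which the relevance-propagation step relies on (it needs direct
access to every weight matrix and activation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import (
    GenotypeMatrix,
    PhenotypeVector,
    StandardizationStats,
    stratified_split,
)

_CLIP = 1e-12  # probability clip inside the cross-entropy


@dataclass
class TrainingConfig:
    """Hyperparameters of the classification step.

    Defaults are the generated-data profile: tau=1e-4, upsilon=1e-6,
    dropout 0.3, learning rate 0.01 with plateau reduction (factor 0.7125
    after 50 epochs without validation-loss improvement), 500 epochs.
    ``kappa`` is an optional p-value prefilter on SNPs (1 = keep all).
    """

    n_neurons: int = 64
    tau: float = 1e-4            # L1 coefficient
    upsilon: float = 1e-6        # L2 (squared) coefficient
    dropout: float = 0.3
    learning_rate: float = 0.01
    epochs: int = 500
    batch_size: int = 32
    lr_plateau_factor: float = 0.7125
    lr_plateau_patience: int = 50
    class_weights: tuple[float, float] | None = None  # None = n/(2*n_class)
    seed: int = 0
    kappa: float = 1.0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.tau < 0 or self.upsilon < 0:
            raise ValueError("regularization coefficients must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    @classmethod
    def wtccc_profile(cls, **overrides) -> "TrainingConfig":
        """The real-data profile: heavier regularization, slow learning rate,
        kappa = 1e-2 prefilter."""
        cfg = cls(tau=1e-3, upsilon=1e-4, learning_rate=1e-5, kappa=1e-2)
        return replace(cfg, **overrides)


@dataclass
class NetworkParameters:
    """Per-layer weights/biases; activations are (relu, relu, softmax)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "NetworkParameters":
        return NetworkParameters([w.copy() for w in self.weights],
                                 [b.copy() for b in self.biases])


@dataclass
class TrainedModel:
    params: NetworkParameters
    stats: StandardizationStats | None
    feature_mask: np.ndarray | None      # kappa-selected SNP mask, length d
    history: dict = field(default_factory=dict)
    config: TrainingConfig | None = None


def pvalue_prefilter(
    g: GenotypeMatrix, y: PhenotypeVector, kappa: float
) -> tuple[np.ndarray, GenotypeMatrix]:
    """Keep SNPs whose chi-square p-value is below ``kappa``.

    Filtered-out SNPs take no part in training or relevance propagation and
    are later reported with relevance 0 and p-value 1.
    """
    from .association import chi2_pvalues_all

    if not 0 < kappa <= 1:
        raise ValueError("kappa must be in (0, 1]")
    if kappa == 1.0:
        return np.ones(g.n_snps, dtype=bool), g
    mask = chi2_pvalues_all(g, y) < kappa
    if not mask.any():
        raise ValueError("prefilter removed every SNP; increase kappa")
    return mask, g.subset_snps(mask)


def init_parameters(
    n_inputs: int, n_neurons: int, rng: np.random.Generator, dtype=np.float32
) -> NetworkParameters:
    """He-scaled Gaussian init for the ReLU layers, Glorot for the softmax head."""
    sizes = [n_inputs, n_neurons, n_neurons, 2]
    weights, biases = [], []
    for q in range(3):
        fan_in, fan_out = sizes[q], sizes[q + 1]
        scale = np.sqrt(2.0 / fan_in) if q < 2 else np.sqrt(2.0 / (fan_in + fan_out))
        weights.append((rng.standard_normal((fan_in, fan_out)) * scale).astype(dtype))
        biases.append(np.zeros(fan_out, dtype=dtype))
    return NetworkParameters(weights, biases)


def forward(
    params: NetworkParameters,
    x: np.ndarray,
    dropout_masks: list[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Return the activation list [input, hidden1, hidden2, logits].

    ``dropout_masks`` (training only) are inverted-dropout multipliers applied
    after each hidden ReLU.
    """
    a = x
    acts = [a]
    for q in range(3):
        z = a @ params.weights[q] + params.biases[q]
        if q < 2:
            a = np.maximum(z, 0)
            if dropout_masks is not None:
                a = a * dropout_masks[q]
        else:
            a = z  # logits; softmax applied where probabilities are needed
        acts.append(a)
    return acts


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def balanced_class_weights(y: np.ndarray) -> np.ndarray:
    """Per-class multipliers n / (2 * n_class)."""
    n = y.shape[0]
    return np.array([n / (2.0 * (y == c).sum()) for c in (0, 1)])


def loss(
    y_true: np.ndarray,
    y_prob: np.ndarray,
    params: NetworkParameters | None = None,
    tau: float = 0.0,
    upsilon: float = 0.0,
    class_weights: np.ndarray | None = None,
) -> float:
    """Class-weighted cross-entropy plus ``tau*sum|W| + upsilon*sum W^2``.

    ``y_prob`` is the predicted case probability. The data term is the
    weighted mean over samples (weights normalized to unit mean), so
    duplicating samples with weights reset to one leaves it unchanged.
    """
    y_true = np.asarray(y_true)
    p_case = np.clip(np.asarray(y_prob, dtype=float), _CLIP, 1 - _CLIP)
    ce = -(y_true * np.log(p_case) + (1 - y_true) * np.log(1 - p_case))
    if class_weights is None:
        w = np.ones_like(ce)
    else:
        w = np.asarray(class_weights, dtype=float)[y_true]
    total = float((w * ce).sum() / w.sum())
    if params is not None:
        for W in params.weights:
            total += tau * float(np.abs(W).sum()) + upsilon * float((W ** 2).sum())
    return total


def loss_and_gradients(
    params: NetworkParameters,
    x: np.ndarray,
    y: np.ndarray,
    sample_weights: np.ndarray,
    tau: float,
    upsilon: float,
    dropout_masks: list[np.ndarray] | None = None,
):
    """Full loss and analytic gradients w.r.t. every weight and bias."""
    acts = forward(params, x, dropout_masks)
    probs = softmax(acts[-1])
    w = np.asarray(sample_weights, dtype=x.dtype)  # keep the matmul dtype uniform
    wsum = w.sum()
    p_case = np.clip(probs[:, 1].astype(np.float64), _CLIP, 1 - _CLIP)
    ce = -(y * np.log(p_case) + (1 - y) * np.log(1 - p_case))
    data_loss = float((w * ce).sum() / wsum)
    reg = 0.0
    if tau != 0.0 or upsilon != 0.0:
        reg = sum(
            tau * float(np.abs(W).sum()) + upsilon * float((W ** 2).sum())
            for W in params.weights
        )

    onehot = np.zeros_like(probs)
    onehot[np.arange(y.shape[0]), y] = 1.0
    delta = (probs - onehot) * (w / wsum)[:, None]
    grads_w, grads_b = [None] * 3, [None] * 3
    for q in (2, 1, 0):
        a_prev = acts[q]
        grads_w[q] = a_prev.T @ delta
        if tau != 0.0:
            grads_w[q] += tau * np.sign(params.weights[q])
        if upsilon != 0.0:
            grads_w[q] += 2.0 * upsilon * params.weights[q]
        grads_b[q] = delta.sum(axis=0)
        if q > 0:
            delta = delta @ params.weights[q].T
            if dropout_masks is not None:
                delta = delta * dropout_masks[q - 1]
            delta = delta * (acts[q] > 0)
    return data_loss + reg, grads_w, grads_b, probs


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional speedup
    _njit = None


def _adam_update_numpy(p, m, v, g, lr, corr1, corr2, b1, b2, eps, tau, upsilon):
    g = g + tau * np.sign(p) + 2.0 * upsilon * p
    m *= b1
    m += (1 - b1) * g
    v *= b2
    v += (1 - b2) * np.square(g)
    p -= lr * (m / corr1) / (np.sqrt(v / corr2) + eps)


if _njit is not None:
    # fused single-pass kernel: penalty gradient + Adam moments + update.
    # All scalars arrive pre-cast to the array dtype so the loop vectorizes.
    @_njit(cache=True, fastmath=True)
    def _adam_kernel(p, m, v, g, step_size, inv_sqrt_corr2, b1, b2, eps, tau, ups2):
        one = p.dtype.type(1.0)
        zero = p.dtype.type(0.0)
        for i in range(p.shape[0]):
            gi = g[i]
            pi = p[i]
            if tau != zero or ups2 != zero:
                s = one if pi > zero else (-one if pi < zero else zero)
                gi = gi + tau * s + ups2 * pi
            mi = b1 * m[i] + (one - b1) * gi
            vi = b2 * v[i] + (one - b2) * gi * gi
            m[i] = mi
            v[i] = vi
            p[i] = pi - step_size * mi / (np.sqrt(vi) * inv_sqrt_corr2 + eps)

    def _adam_update(p, m, v, g, lr, corr1, corr2, b1, b2, eps, tau, upsilon):
        dt = p.dtype.type
        _adam_kernel(
            p, m, v, g, dt(lr / corr1), dt(1.0 / np.sqrt(corr2)),
            dt(b1), dt(b2), dt(eps), dt(tau), dt(2.0 * upsilon),
        )
else:  # pragma: no cover
    _adam_update = _adam_update_numpy


class _Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8), in-place updates.

    The L1/L2 penalty gradients are folded into the update so the training
    loop can compute pure data gradients; the resulting iterates are
    identical to feeding the full analytic gradient to textbook Adam.
    """

    def __init__(self, params: NetworkParameters, tau: float = 0.0, upsilon: float = 0.0):
        self.m = [np.zeros_like(w) for w in params.weights + params.biases]
        self.v = [np.zeros_like(w) for w in params.weights + params.biases]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.tau, self.upsilon = tau, upsilon

    def step(self, params: NetworkParameters, grads: list[np.ndarray], lr: float):
        self.t += 1
        corr1 = 1 - self.b1 ** self.t
        corr2 = 1 - self.b2 ** self.t
        tensors = params.weights + params.biases
        n_weights = len(params.weights)
        for k, (p, g) in enumerate(zip(tensors, grads)):
            g = np.ascontiguousarray(g, dtype=p.dtype)
            tau, ups = (self.tau, self.upsilon) if k < n_weights else (0.0, 0.0)
            _adam_update(
                p.reshape(-1), self.m[k].reshape(-1), self.v[k].reshape(-1),
                g.reshape(-1), lr, corr1, corr2, self.b1, self.b2, self.eps,
                tau, ups,
            )


def train(
    x_features: np.ndarray,
    y: PhenotypeVector | np.ndarray,
    cfg: TrainingConfig | None = None,
    stats: StandardizationStats | None = None,
    feature_mask: np.ndarray | None = None,
) -> TrainedModel:
    """Fixed-epoch Adam training of the 64-64 softmax network.

    ``x_features`` must already be standardized. A stratified 10% slice of the
    training data monitors validation loss for the plateau schedule. Training
    is deterministic under a fixed seed.
    """
    cfg = cfg or TrainingConfig()
    labels = y.labels if isinstance(y, PhenotypeVector) else np.asarray(y)
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("both classes must be present in the training data")
    x_features = np.ascontiguousarray(x_features, dtype=np.float32)
    rng = np.random.default_rng(cfg.seed)

    split = stratified_split(
        PhenotypeVector(labels), 1 - cfg.validation_fraction, seed=cfg.seed + 1
    )
    x_tr, y_tr = x_features[split.train_indices], labels[split.train_indices]
    x_va, y_va = x_features[split.test_indices], labels[split.test_indices]

    cw = (
        np.asarray(cfg.class_weights, dtype=float)
        if cfg.class_weights is not None
        else balanced_class_weights(y_tr)
    )
    params = init_parameters(x_features.shape[1], cfg.n_neurons, rng)
    adam = _Adam(params, cfg.tau, cfg.upsilon)
    lr = cfg.learning_rate
    best_val, stall = np.inf, 0
    history = {"loss": [], "val_loss": [], "accuracy": [], "val_accuracy": [], "lr": []}

    n_tr = x_tr.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_tr)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            masks = None
            if cfg.dropout > 0:
                keep = 1.0 - cfg.dropout
                masks = [
                    (rng.random((xb.shape[0], cfg.n_neurons)) < keep).astype(np.float32)
                    / keep
                    for _ in range(2)
                ]
            # penalty gradients are applied inside the Adam kernel
            batch_loss, gw, gb, probs = loss_and_gradients(
                params, xb, yb, cw[yb], 0.0, 0.0, masks
            )
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={batch_loss!r}, "
                    f"lr={lr:.3g}"
                )
            adam.step(params, gw + gb, lr)
            ep_loss += batch_loss * xb.shape[0]
            ep_correct += int((probs.argmax(axis=1) == yb).sum())

        # training-mode epoch metrics (batch averages); validation in inference mode
        reg = sum(
            cfg.tau * float(np.abs(W).sum()) + cfg.upsilon * float((W ** 2).sum())
            for W in params.weights
        )
        va_loss, va_acc = _evaluate(params, x_va, y_va, cw, cfg)
        history["loss"].append(ep_loss / n_tr + reg)
        history["val_loss"].append(va_loss)
        history["accuracy"].append(ep_correct / n_tr)
        history["val_accuracy"].append(va_acc)
        history["lr"].append(lr)
        if va_loss < best_val - 1e-7:
            best_val, stall = va_loss, 0
        else:
            stall += 1
            if stall >= cfg.lr_plateau_patience:
                lr *= cfg.lr_plateau_factor
                stall = 0

    return TrainedModel(params, stats, feature_mask, history, cfg)


def _evaluate(params, x, y, class_weights, cfg):
    probs = softmax(forward(params, x)[-1])
    ls = loss(y, probs[:, 1], params, cfg.tau, cfg.upsilon, class_weights)
    acc = float((probs.argmax(axis=1) == y).mean())
    return ls, acc


def predict(
    model: TrainedModel, x_features: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labels, softmax probabilities and pre-softmax scores (dropout off)."""
    x_features = np.asarray(x_features, dtype=np.float32)
    if x_features.shape[1] != model.params.weights[0].shape[0]:
        raise ValueError(
            f"feature width {x_features.shape[1]} does not match network input "
            f"{model.params.weights[0].shape[0]}"
        )
    logits = forward(model.params, x_features)[-1]
    probs = softmax(logits)
    return probs.argmax(axis=1), probs, logits


def accuracy(model: TrainedModel, x_features: np.ndarray, y) -> float:
    labels = y.labels if isinstance(y, PhenotypeVector) else np.asarray(y)
    pred, _, _ = predict(model, x_features)
    return float((pred == labels).mean())
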