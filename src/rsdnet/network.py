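"""Feed-forward binary classifier trained by backpropagation with Nadam.

Architecture: tanh hidden layers (default 5 and 3 units) and a 2-unit
softmax output.  The per-batch objective is

    mean cross-entropy  +  sum over layers of penalty(kernel),

where the penalty is any :class:`~rsdnet.regularizers.Regularizer` (the RSD
standard-deviation penalty or an L1/L2/elastic-net baseline).  Penalties act
on kernel matrices only; bias gradients carry no penalty term.  The penalty
is added once per batch, not scaled by batch size.

Nadam (Adam with a Nesterov lookahead in the first moment) update, with step
index t starting at 1:

    m <- b1*m + (1-b1)*g          v <- b2*v + (1-b2)*g^2
    m_hat = m/(1-b1^t)            v_hat = v/(1-b2^t)
    theta <- theta - lr * (b1*m_hat + (1-b1)*g/(1-b1^t)) / (sqrt(v_hat) + eps)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .preprocess import FeatureTable
from .regularizers import Regularizer

PROB_FLOOR = 1e-12


@dataclass
class TrainConfig:
    """Training hyperparameters for the mini-batch Nadam loop."""

    epochs: int = 100
    batch_size: int = 4
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps_opt: float = 1e-8
    init_std: float = 0.05
    seed: int = 0
    regularizer: Regularizer = field(default_factory=Regularizer)
    hidden_layer_sizes: tuple = (5, 3)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1 and beta2 must lie in [0, 1)")


def init_network(layer_sizes, init_std: float, seed: int) -> list:
    """Gaussian-initialized kernels (std ``init_std``), zero biases.

    Returns an ordered list of (kernel, bias) pairs; identical seeds give
    bit-identical parameters.
    """
    sizes = list(layer_sizes)
    if len(sizes) < 2:
        raise ValueError("need at least an input and an output layer size")
    rng = np.random.default_rng(seed)
    params = []
    for d_in, d_out in zip(sizes[:-1], sizes[1:]):
        w = rng.normal(0.0, init_std, size=(d_in, d_out))
        params.append((w, np.zeros(d_out)))
    return params


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(params, X) -> list:
    """Per-layer activations; the last entry holds softmax class probabilities."""
    a = np.asarray(X, dtype=float)
    if a.ndim != 2 or a.shape[1] != params[0][0].shape[0]:
        raise ValueError(
            f"input has shape {a.shape}, expected (*, {params[0][0].shape[0]})"
        )
    activations = []
    for i, (w, b) in enumerate(params):
        z = a @ w + b
        a = _softmax(z) if i == len(params) - 1 else np.tanh(z)
        activations.append(a)
    return activations


def cross_entropy(probs, one_hot) -> float:
    """Mean negative log-likelihood of the true class, probabilities floored
    at 1e-12 before the log."""
    probs = np.asarray(probs, dtype=float)
    one_hot = np.asarray(one_hot, dtype=float)
    if probs.shape != one_hot.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {one_hot.shape}")
    return float(
        -(one_hot * np.log(np.maximum(probs, PROB_FLOOR))).sum() / probs.shape[0]
    )


def penalized_loss(params, X, one_hot, reg: Regularizer) -> float:
    probs = forward(params, X)[-1]
    return cross_entropy(probs, one_hot) + sum(reg.penalty(w) for w, _ in params)


def backward(params, X, one_hot, reg: Regularizer) -> list:
    """Gradients of [mean cross-entropy + sum penalty(kernel)] w.r.t. every
    kernel and bias; same shapes as ``params``."""
    X = np.asarray(X, dtype=float)
    one_hot = np.asarray(one_hot, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    acts = forward(params, X)
    n = X.shape[0]
    # softmax + mean cross-entropy: delta at the output pre-activation
    delta = (acts[-1] - one_hot) / n
    grads = [None] * len(params)
    for i in range(len(params) - 1, -1, -1):
        a_prev = X if i == 0 else acts[i - 1]
        w, _ = params[i]
        gw = a_prev.T @ delta + reg.grad(w)
        gb = delta.sum(axis=0)
        grads[i] = (gw, gb)
        if i > 0:
            delta = (delta @ w.T) * (1.0 - acts[i - 1] ** 2)
    return grads


def init_opt_state(params) -> list:
    return [
        (np.zeros_like(w), np.zeros_like(w), np.zeros_like(b), np.zeros_like(b))
        for w, b in params
    ]


def nadam_step(params, grads, opt_state, config: TrainConfig, t: int):
    """One Nadam update; returns (new params, new state)."""
    if t < 1:
        raise ValueError("step index t must be >= 1")
    b1, b2 = config.beta1, config.beta2
    lr, eps = config.learning_rate, config.eps_opt
    c1, c2 = 1.0 - b1 ** t, 1.0 - b2 ** t
    new_params, new_state = [], []
    for (w, b), (gw, gb), (mw, vw, mb, vb) in zip(params, grads, opt_state):
        upd = []
        for theta, g, m, v in ((w, gw, mw, vw), (b, gb, mb, vb)):
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            m_hat = m / c1
            v_hat = v / c2
            step = lr * (b1 * m_hat + (1 - b1) * g / c1) / (np.sqrt(v_hat) + eps)
            upd.append((theta - step, m, v))
        (w2, mw, vw), (b2_, mb, vb) = upd
        new_params.append((w2, b2_))
        new_state.append((mw, vw, mb, vb))
    return new_params, new_state


def _one_hot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((len(y), 2))
    out[np.arange(len(y)), y] = 1.0
    return out


class RSDNetClassifier(ClassifierMixin, BaseEstimator):
    """Feed-forward tanh/softmax binary classifier with a pluggable penalty.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int, default (5, 3)
        Hidden-layer widths; the output layer always has 2 softmax units.
    family : {"none", "l1", "l2", "elastic", "rsd"}
        Penalty applied to every kernel matrix.
    lam : float
        Penalty strength lambda.
    alpha : float
        Elastic-net mixing parameter (ignored by other families).
    rsd_mode : {"flat", "rowwise"}
        How the RSD penalty's sigma aggregates over a kernel.
    epochs, batch_size, learning_rate, beta1, beta2, eps, init_std
        Training-loop and Nadam hyperparameters.
    random_state : int
        Seeds both the Gaussian kernel initialization and the per-epoch
        shuffles; identical seeds give identical training histories.

    Attributes
    ----------
    coefs_ : list of ndarray
        Fitted kernel matrices, one per layer.
    intercepts_ : list of ndarray
        Fitted bias vectors.
    classes_ : ndarray
        Sorted class labels; index 0 is the tie-break winner at exactly
        0.5/0.5 output.
    history_ : pandas.DataFrame
        Per-epoch training loss, training accuracy and (if validation data
        was supplied) validation accuracy.
    """

    def __init__(
        self,
        hidden_layer_sizes=(5, 3),
        family: str = "none",
        lam: float = 0.0,
        alpha: float = 0.5,
        rsd_mode: str = "flat",
        epochs: int = 100,
        batch_size: int = 4,
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        init_std: float = 0.05,
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.family = family
        self.lam = lam
        self.alpha = alpha
        self.rsd_mode = rsd_mode
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.init_std = init_std
        self.random_state = random_state

    def _regularizer(self) -> Regularizer:
        return Regularizer(
            family=self.family, lam=self.lam, alpha=self.alpha, rsd_mode=self.rsd_mode
        )

    def fit(self, X, y, validation_data=None):
        X = check_array(X)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("training set is empty")
        self.classes_ = np.unique(y)
        if len(self.classes_) > 2:
            raise ValueError("only binary classification is supported")
        codes = np.searchsorted(self.classes_, y)
        reg = self._regularizer()
        cfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            eps_opt=self.eps,
            init_std=self.init_std,
            seed=self.random_state,
            regularizer=reg,
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
        )

        sizes = [X.shape[1], *cfg.hidden_layer_sizes, 2]
        rng = np.random.default_rng(cfg.seed)
        params = []
        for d_in, d_out in zip(sizes[:-1], sizes[1:]):
            params.append((rng.normal(0.0, cfg.init_std, size=(d_in, d_out)),
                           np.zeros(d_out)))

        one_hot = _one_hot(codes)
        if validation_data is not None:
            X_val = check_array(validation_data[0])
            y_val_codes = np.searchsorted(self.classes_, np.asarray(validation_data[1]))
        state = init_opt_state(params)
        t = 0
        n = X.shape[0]
        hist = {"loss": [], "train_accuracy": [], "val_accuracy": []}
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                grads = backward(params, X[idx], one_hot[idx], reg)
                t += 1
                params, state = nadam_step(params, grads, state, cfg, t)
            probs = forward(params, X)[-1]
            hist["loss"].append(
                cross_entropy(probs, one_hot) + sum(reg.penalty(w) for w, _ in params)
            )
            hist["train_accuracy"].append(float((probs.argmax(axis=1) == codes).mean()))
            if validation_data is not None:
                val_pred = forward(params, X_val)[-1].argmax(axis=1)
                hist["val_accuracy"].append(float((val_pred == y_val_codes).mean()))
            else:
                hist["val_accuracy"].append(np.nan)
        self.coefs_ = [w for w, _ in params]
        self.intercepts_ = [b for _, b in params]
        self.history_ = pd.DataFrame(hist)
        self.n_iter_ = cfg.epochs
        self.n_features_in_ = X.shape[1]
        return self

    def _params(self):
        return list(zip(self.coefs_, self.intercepts_))

    def predict_proba(self, X):
        check_is_fitted(self, "coefs_")
        X = check_array(X)
        return forward(self._params(), X)[-1]

    def predict(self, X):
        # argmax takes the first maximum, so an exact 0.5/0.5 tie resolves to
        # the lower class label
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]


def train(train_table: FeatureTable, val_table: FeatureTable | None, config: TrainConfig):
    """Train on a preprocessed table; returns (params, history DataFrame)."""
    clf = RSDNetClassifier(
        hidden_layer_sizes=config.hidden_layer_sizes,
        family=config.regularizer.family,
        lam=config.regularizer.lam,
        alpha=config.regularizer.alpha,
        rsd_mode=config.regularizer.rsd_mode,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        eps=config.eps_opt,
        init_std=config.init_std,
        random_state=config.seed,
    )
    val = None if val_table is None else (val_table.values, val_table.labels)
    clf.fit(train_table.values, train_table.labels, validation_data=val)
    return list(zip(clf.coefs_, clf.intercepts_)), clf.history_
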