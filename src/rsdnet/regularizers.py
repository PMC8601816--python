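"""Weight-decay penalties and their gradients.

The package's central object is the RSD penalty: lambda times the population
standard deviation of a layer's weight matrix,

    penalty(W) = lam * sqrt( mean(W**2) - mean(W)**2 ).

Unlike L1/L2/elastic net, the RSD penalty is invariant to adding a constant
to every weight (it penalizes dispersion, not magnitude) and is absolutely
homogeneous of degree one.  Classical baselines (lasso, ridge, elastic net)
are provided in the same interface so they can be swapped into the network's
training loop.

Penalties apply to kernel (weight) matrices only, never to bias vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FAMILIES = ("none", "l1", "l2", "elastic", "rsd")

#: guard added to sigma in the RSD gradient denominator so constant matrices
#: (sigma = 0, numerator identically 0) yield a zero gradient instead of 0/0
RSD_EPS = 1e-12


def _as_array(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("weight matrix must have at least one entry")
    if not np.all(np.isfinite(w)):
        raise ValueError("weight matrix contains non-finite entries")
    return w


def _check_lambda(lam: float) -> float:
    lam = float(lam)
    if lam < 0:
        raise ValueError(f"lambda must be nonnegative, got {lam}")
    return lam


def penalty_l1(w, lam: float) -> float:
    """Lasso penalty: lam * sum of absolute weight values."""
    return _check_lambda(lam) * float(np.abs(_as_array(w)).sum())


def penalty_l2(w, lam: float) -> float:
    """Ridge penalty: lam * sum of squared weights (no 1/2 factor)."""
    return _check_lambda(lam) * float(np.square(_as_array(w)).sum())


def penalty_elastic(w, lam: float, alpha: float) -> float:
    """Elastic-net penalty: lam * sum[ ((1-alpha)/2) w^2 + alpha |w| ].

    ``alpha=1`` reduces to the lasso penalty, ``alpha=0`` to half the ridge
    penalty.
    """
    alpha = float(alpha)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    w = _as_array(w)
    return _check_lambda(lam) * float(
        0.5 * (1.0 - alpha) * np.square(w).sum() + alpha * np.abs(w).sum()
    )


def penalty_rsd(w, lam: float, mode: str = "flat") -> float:
    """Standard-deviation penalty: lam * population sigma of the weights.

    ``mode="flat"`` (default) computes sigma over all entries of the matrix
    flattened.  ``mode="rowwise"`` sums the per-row sigmas instead, treating
    each row of the kernel as its own weight vector.
    """
    w = _as_array(w)
    lam = _check_lambda(lam)
    if mode == "flat":
        return lam * float(w.std())
    if mode == "rowwise":
        return lam * float(np.atleast_2d(w).std(axis=1).sum())
    raise ValueError(f"unknown rsd mode {mode!r}")


def _grad_rsd(w: np.ndarray, lam: float, mode: str) -> np.ndarray:
    if mode == "flat":
        sigma = w.std()
        return lam * (w - w.mean()) / (w.size * (sigma + RSD_EPS))
    if mode == "rowwise":
        w2 = np.atleast_2d(w)
        sigma = w2.std(axis=1, keepdims=True)
        g = lam * (w2 - w2.mean(axis=1, keepdims=True)) / (
            w2.shape[1] * (sigma + RSD_EPS)
        )
        return g.reshape(w.shape)
    raise ValueError(f"unknown rsd mode {mode!r}")


@dataclass(frozen=True)
class Regularizer:
    """Penalty family plus its strength lambda (and mixing alpha for elastic).

    Parameters
    ----------
    family : {"none", "l1", "l2", "elastic", "rsd"}
    lam : float
        Regularization strength, >= 0.
    alpha : float
        Elastic-net mixing parameter in [0, 1]; used only by ``family="elastic"``.
    rsd_mode : {"flat", "rowwise"}
        Whether the RSD sigma is taken over the flattened kernel or summed
        over its rows.
    """

    family: str = "none"
    lam: float = 0.0
    alpha: float = 0.5
    rsd_mode: str = "flat"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown regularizer family {self.family!r}; choose from {FAMILIES}"
            )
        _check_lambda(self.lam)
        if self.family == "elastic" and not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.rsd_mode not in ("flat", "rowwise"):
            raise ValueError(f"unknown rsd mode {self.rsd_mode!r}")

    def penalty(self, w) -> float:
        if self.family == "none" or self.lam == 0.0:
            return 0.0
        if self.family == "l1":
            return penalty_l1(w, self.lam)
        if self.family == "l2":
            return penalty_l2(w, self.lam)
        if self.family == "elastic":
            return penalty_elastic(w, self.lam, self.alpha)
        return penalty_rsd(w, self.lam, self.rsd_mode)

    def grad(self, w) -> np.ndarray:
        w = _as_array(w)
        if self.family == "none" or self.lam == 0.0:
            return np.zeros_like(w)
        if self.family == "l1":
            return self.lam * np.sign(w)
        if self.family == "l2":
            return 2.0 * self.lam * w
        if self.family == "elastic":
            return self.lam * ((1.0 - self.alpha) * w + self.alpha * np.sign(w))
        return _grad_rsd(w, self.lam, self.rsd_mode)


def grad_penalty(w, spec: Regularizer) -> np.ndarray:
    """Elementwise gradient of ``spec``'s penalty at ``w`` (same shape as ``w``).

    Subgradient convention at kinks: sign(0) = 0 for l1/elastic, which keeps
    exactly-zero weights at zero.
    """
    return spec.grad(w)
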