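"""Weighted voxel-wise focal loss for extreme class imbalance.

Fractured-femur label volumes are dominated by background (roughly
9800:200:1 background:bone:gap), so plain cross-entropy lets the easy
background voxels drown out the fracture gap.  The focal modulation
(1-p)^γ suppresses well-classified voxels; per-class weights w re-balance
the three classes.  Defaults: γ = 2, w = (0.15, 0.25, 0.6).

Each class channel is scored one-vs-rest against its one-hot target, the
per-class focal terms are averaged over all voxels, weighted and summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

EPS = 1e-7

DEFAULT_GAMMA = 2.0
DEFAULT_WEIGHTS = (0.15, 0.25, 0.6)


@dataclass
class FocalLossParams:
    gamma: float = DEFAULT_GAMMA
    weights: tuple[float, ...] = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 5.0):
            raise ValueError("focusing parameter gamma must lie in [0, 5]")
        if any(w < 0 for w in self.weights):
            raise ValueError("class weights must be nonnegative")

    def for_n_classes(self, n: int) -> "FocalLossParams":
        """Truncate and renormalise weights for an n-class network."""
        if n == len(self.weights):
            return self
        w = np.array(self.weights[:n], dtype=float)
        return FocalLossParams(self.gamma, tuple(w / w.sum()))


def focal_term(p: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    """Per-voxel focal term, nonnegative.

    y = 1: -(1-p)^γ log p ;  y = 0: -p^γ log(1-p).  Probabilities are
    clamped at EPS for numerical safety.
    """
    p = np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)
    y = np.asarray(y)
    pos = -((1.0 - p) ** gamma) * np.log(p)
    neg = -(p**gamma) * np.log(1.0 - p)
    return np.where(y == 1, pos, neg)


def focal_term_grad(p: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    """Analytic d(focal_term)/dp, matching the clamped forward pass."""
    p = np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)
    y = np.asarray(y)
    if gamma == 0.0:
        dpos = -1.0 / p
        dneg = 1.0 / (1.0 - p)
    else:
        dpos = gamma * (1.0 - p) ** (gamma - 1.0) * np.log(p) - (1.0 - p) ** gamma / p
        dneg = -gamma * p ** (gamma - 1.0) * np.log(1.0 - p) + p**gamma / (1.0 - p)
    return np.where(y == 1, dpos, dneg)


def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    target = np.asarray(target)
    out = np.zeros((n_classes,) + target.shape, dtype=float)
    for c in range(n_classes):
        out[c] = target == c
    return out


def focal_loss(
    probs: np.ndarray, target: np.ndarray, params: FocalLossParams | None = None
) -> float:
    """Weighted focal loss of a class-probability volume against labels.

    ``probs`` has the class axis first: (C, ...) summing to 1 along it;
    ``target`` holds integer labels < C with the remaining shape.
    """
    params = params or FocalLossParams()
    probs = np.asarray(probs, dtype=float)
    n_classes = probs.shape[0]
    if probs.shape[1:] != np.asarray(target).shape:
        raise ValueError(
            f"shape mismatch: probs {probs.shape[1:]} vs target {np.asarray(target).shape}"
        )
    if int(np.asarray(target).max(initial=0)) >= n_classes:
        raise ValueError("target contains classes beyond the probability channels")
    p = params.for_n_classes(n_classes)
    onehot = _one_hot(target, n_classes)
    total = 0.0
    for c in range(n_classes):
        total += p.weights[c] * float(focal_term(probs[c], onehot[c], p.gamma).mean())
    return total


def cross_entropy(probs: np.ndarray, target: np.ndarray) -> float:
    """Mean one-vs-rest binary cross-entropy per class, unit weights.

    Equals :func:`focal_loss` at γ = 0 with unit weights; kept as an
    independent reference for tests.
    """
    probs = np.clip(np.asarray(probs, dtype=float), EPS, 1.0 - EPS)
    n_classes = probs.shape[0]
    onehot = _one_hot(target, n_classes)
    total = 0.0
    for c in range(n_classes):
        pc, yc = probs[c], onehot[c]
        total += float((-(yc * np.log(pc)) - (1 - yc) * np.log(1 - pc)).mean())
    return total


def focal_loss_tensor(
    logits: "ad.Tensor", target: np.ndarray, params: FocalLossParams | None = None
) -> "ad.Tensor":
    """Differentiable focal loss on raw network scores.

    ``logits`` is (N, C, ...); ``target`` integer labels (N, ...).  Applies
    log-softmax over the class axis, then the same weighted one-vs-rest
    focal reduction as :func:`focal_loss`.
    """
    params = params or FocalLossParams()
    n_classes = logits.shape[1]
    p = params.for_n_classes(n_classes)
    lsm = ad.log_softmax(logits, axis=1)
    probs = ad.clamp(ad.exp(lsm), EPS, 1.0 - EPS)
    target = np.asarray(target)
    total = None
    for c in range(n_classes):
        yc = (target == c).astype(logits.data.dtype)[:, None]
        pc = _take_channel(probs, c)
        logp = ad.log(pc)
        log1mp = ad.log(ad.clamp(1.0 - pc, EPS, 1.0))
        yc_t = ad.Tensor(yc)
        pos = ad.mul(ad.pow_const(1.0 - pc, p.gamma), logp)
        neg = ad.mul(ad.pow_const(pc, p.gamma), log1mp)
        term = -(yc_t * pos + (1.0 - yc_t) * neg)
        contrib = p.weights[c] * ad.mean(term)
        total = contrib if total is None else total + contrib
    return total


def _take_channel(x: "ad.Tensor", c: int) -> "ad.Tensor":
    """Slice channel c of (N, C, ...) keeping the channel axis."""
    idx = (slice(None), slice(c, c + 1))
    data = x.data[idx]

    def backward(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        return (full,)

    return ad._node(data, (x,), backward)
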