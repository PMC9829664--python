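"""Scikit-learn style estimator wrapping the reconstruction network.

`FracReconNet` follows the sklearn estimator contract (``get_params`` /
``set_params`` via ``BaseEstimator``, ``fit`` / ``predict`` /
``predict_proba``, fitted attributes with a trailing underscore) so it
composes with sklearn model selection.  X is an array of radiograph pairs
(n_samples, 2, H, W) in [0, 1]; y is an array of integer label volumes
(n_samples, D, H, W) in network layout.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_random_state

from . import autodiff as ad
from .losses import FocalLossParams, focal_loss_tensor
from .model import NetworkConfig, ReconNet3D, softmax_probabilities


class EarlyStopping:
    """Stop when the monitored loss fails to improve ``patience`` times."""

    def __init__(self, patience: int = 10, min_delta: float = 0.0):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_rounds = 0
        self.best_round = -1
        self.round = -1

    def update(self, loss: float) -> bool:
        """Record one evaluation; returns True when training should stop."""
        self.round += 1
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_round = self.round
            self.bad_rounds = 0
        else:
            self.bad_rounds += 1
        return self.bad_rounds >= self.patience


class FracReconNet(BaseEstimator):
    """Biplanar-radiograph → 3D label-volume reconstruction estimator.

    Parameters mirror the network/training configuration: pyramid depth and
    widths, focal-loss focusing parameter and class weights, Adam settings,
    and the early-stopping patience (active when a validation set is given
    to :meth:`fit`).  ``n_classes=3`` enables the fracture-gap auxiliary
    class; ``n_classes=2`` is the plain background/bone variant.
    """

    def __init__(
        self,
        levels: int = 4,
        image_size: int = 32,
        n_classes: int = 3,
        base_channels: int = 8,
        growth: int = 4,
        dense_layers: int = 4,
        channels_3d: int = 4,
        up_channels: int = 8,
        fusion_channels: int = 8,
        fusion_convs: int = 2,
        gamma: float = 2.0,
        class_weights: tuple[float, ...] = (0.15, 0.25, 0.6),
        learning_rate: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.99,
        batch_size: int = 1,
        max_steps: int = 200,
        eval_every: int = 10,
        patience: int = 10,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.levels = levels
        self.image_size = image_size
        self.n_classes = n_classes
        self.base_channels = base_channels
        self.growth = growth
        self.dense_layers = dense_layers
        self.channels_3d = channels_3d
        self.up_channels = up_channels
        self.fusion_channels = fusion_channels
        self.fusion_convs = fusion_convs
        self.gamma = gamma
        self.class_weights = class_weights
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.eval_every = eval_every
        self.patience = patience
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers -----------------------------------------------------------
    def _network_config(self, seed: int) -> NetworkConfig:
        return NetworkConfig(
            levels=self.levels,
            image_size=self.image_size,
            n_classes=self.n_classes,
            base_channels=self.base_channels,
            growth=self.growth,
            dense_layers=self.dense_layers,
            channels_3d=self.channels_3d,
            up_channels=self.up_channels,
            fusion_channels=self.fusion_channels,
            fusion_convs=self.fusion_convs,
            seed=seed,
        )

    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1] != 2:
            raise ValueError(f"X must be (n_samples, 2, H, W), got {X.shape}")
        if X.shape[2] != self.image_size or X.shape[3] != self.image_size:
            raise ValueError(
                f"radiograph extent {X.shape[2:]} != image_size {self.image_size}"
            )
        if y is None:
            return X, None
        y = np.asarray(y)
        if y.ndim != 4 or y.shape[0] != X.shape[0]:
            raise ValueError(f"y must be (n_samples, D, H, W), got {y.shape}")
        if y.max(initial=0) >= self.n_classes:
            raise ValueError("y contains labels beyond n_classes")
        return X, y.astype(np.int64)

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train with Adam on the weighted focal loss.

        When a validation pair ``(X_val, y_val)`` is supplied, the
        validation loss is evaluated every ``eval_every`` steps and training
        stops early after ``patience`` non-improving evaluations; the
        best-validation weights are restored.
        """
        X, y = self._validate_xy(X, y)
        rng = check_random_state(self.random_state)
        seed = int(rng.randint(0, 2**31 - 1))
        self.network_config_ = self._network_config(seed)
        self.net_ = ReconNet3D(self.network_config_)
        params = self.net_.parameters()
        opt = ad.Adam(
            params, lr=self.learning_rate, betas=(self.beta1, self.beta2)
        )
        loss_params = FocalLossParams(self.gamma, self.class_weights).for_n_classes(
            self.n_classes
        )
        has_val = X_val is not None and y_val is not None
        if has_val:
            X_val, y_val = self._validate_xy(X_val, y_val)
            stopper = EarlyStopping(self.patience)
        best_state = None
        order = np.arange(X.shape[0])
        cursor = X.shape[0]  # force reshuffle on first step
        self.history_ = []
        self.loss_curve_ = []
        stop = False
        for step in range(self.max_steps):
            if cursor + self.batch_size > order.size:
                rng.shuffle(order)
                cursor = 0
            idx = order[cursor : cursor + self.batch_size]
            cursor += self.batch_size
            xb = ad.Tensor(X[idx])
            logits = self.net_(xb)
            loss = focal_loss_tensor(logits, y[idx], loss_params)
            opt.zero_grad()
            loss.backward()
            opt.step()
            rec = {"step": step, "train_loss": float(loss.data)}
            self.loss_curve_.append(float(loss.data))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at step {step}: {loss.data}"
                )
            if has_val and (step + 1) % self.eval_every == 0:
                val_loss = self._eval_loss(X_val, y_val, loss_params)
                rec["val_loss"] = val_loss
                if val_loss < stopper.best:
                    best_state = [p.data.copy() for p in params]
                stop = stopper.update(val_loss)
            self.history_.append(rec)
            if self.verbose and (step % max(1, self.max_steps // 20) == 0):
                print(f"step {step}: {rec}")
            if stop:
                break
        if has_val:
            self.best_val_loss_ = stopper.best
            self.stopped_early_ = stop
            if best_state is not None:
                for p, s in zip(params, best_state):
                    p.data = s
        self.n_steps_ = len(self.loss_curve_)
        return self

    def _eval_loss(self, X, y, loss_params) -> float:
        total = 0.0
        for i in range(X.shape[0]):
            logits = self.net_(ad.Tensor(X[i : i + 1]))
            total += float(focal_loss_tensor(logits, y[i : i + 1], loss_params).data)
        return total / X.shape[0]

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("this FracReconNet instance is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        """Per-voxel class probabilities (n_samples, C, D, H, W)."""
        self._check_fitted()
        X, _ = self._validate_xy(X)
        out = []
        for i in range(X.shape[0]):
            logits = self.net_(ad.Tensor(X[i : i + 1]))
            out.append(softmax_probabilities(logits.data)[0])
        return np.stack(out)

    def predict(self, X) -> np.ndarray:
        """Arg-max label volumes (ties resolve to the lower class index)."""
        probs = self.predict_proba(X)
        return probs.argmax(axis=1).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean bone-class IoU over samples (auxiliary merged to background)."""
        from .metrics import iou_arrays

        X, y = self._validate_xy(X, y)
        preds = self.predict(X)
        return float(np.mean([iou_arrays(p, t) for p, t in zip(preds, y)]))

    def clone_with(self, **overrides) -> "FracReconNet":
        params = self.get_params()
        params.update(overrides)
        return FracReconNet(**params)
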