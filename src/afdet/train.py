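"""Training loop for the window classifier.

The loss is two-class softmax cross-entropy on the (l_NSR, l_AFib) logit
pair, which with f = p_AFib is exactly the binary cross-entropy
-(1/n) sum [y log f + (1-y) log(1-f)]. Optimization uses AdamW with cosine
learning-rate decay (standard for ConvNeXt-family models; the choice and all
hyperparameters are exposed in :class:`TrainConfig`). Augmentation is applied
per window from a seeded generator, so a run is reproducible end to end.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .augment import AugmentConfig, augment_window
from .io import WindowSet
from .nn.layers import F32
from .nn.models import Model, softmax

__all__ = ["TrainConfig", "AdamW", "cross_entropy", "train", "predict_windows"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 10
    learning_rate: float = 3e-4
    weight_decay: float = 0.05
    optimizer: str = "adamw"
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    class_weights: tuple[float, float] | None = None
    cosine_decay: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.optimizer.lower() != "adamw":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


class AdamW:
    """Decoupled-weight-decay Adam over a model's parameter dicts."""

    def __init__(self, model: Model, lr: float, weight_decay: float = 0.05,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.model = model
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.slots = list(model.parameters())
        self.m = [np.zeros_like(m.params[k]) for m, k in self.slots]
        self.v = [np.zeros_like(m.params[k]) for m, k in self.slots]

    def step(self, lr_scale: float = 1.0) -> None:
        self.t += 1
        lr = self.lr * lr_scale
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for i, (mod, key) in enumerate(self.slots):
            g = mod.grads[key]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p = mod.params[key]
            # decay weights only (not norm scales/biases would be the usual
            # refinement; decaying everything is simpler and works here)
            p -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)
            mod.params[key] = p.astype(F32, copy=False)


def cross_entropy(logits: np.ndarray, y: np.ndarray,
                  class_weights: np.ndarray | None = None
                  ) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y)
    w = np.ones(n) if class_weights is None else class_weights[y]
    ll = -np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float((w * ll).sum() / w.sum())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad.astype(F32)


def train(model: Model, train_ws: WindowSet, val_ws: WindowSet | None,
          cfg: TrainConfig = TrainConfig(), verbose: bool = False
          ) -> tuple[Model, dict]:
    """Train ``model`` on ``train_ws``; returns the model and a history dict.

    History records per-epoch mean training loss and validation AUROC.
    The parameter state with the best validation AUROC is restored before
    returning (with no validation set, the final state is kept).
    """
    y = np.asarray(train_ws.labels, dtype=np.int64)
    classes = np.unique(y)
    if cfg.epochs > 0 and len(classes) < 2:
        raise ValueError("training set contains a single class; "
                         "cannot fit a binary classifier")
    cw = None
    if cfg.class_weights is not None:
        cw = np.asarray(cfg.class_weights, dtype=np.float64)

    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model, cfg.learning_rate, cfg.weight_decay)
    n = len(train_ws)
    steps_per_epoch = max(1, math.ceil(n / cfg.batch_size))
    total_steps = max(1, cfg.epochs * steps_per_epoch)
    history: dict = {"loss": [], "val_auroc": [], "seed": cfg.seed,
                     "epoch_time_s": []}
    best_auroc, best_state = -np.inf, None

    step = 0
    for epoch in range(cfg.epochs):
        t0 = time.time()
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb = train_ws.data[idx, 0].astype(np.float64)
            yb = y[idx]
            aug = np.empty((len(idx), xb.shape[1]), dtype=F32)
            for j in range(len(idx)):
                xa, _ = augment_window(xb[j], int(yb[j]), cfg.augment, rng,
                                       fs=train_ws.fs)
                aug[j] = xa
            logits = model.forward(aug[:, None, :], train=True)
            loss, dlogits = cross_entropy(logits, yb, cw)
            model.zero_grad()
            model.backward(dlogits)
            lr_scale = (0.5 * (1 + math.cos(math.pi * step / total_steps))
                        if cfg.cosine_decay else 1.0)
            opt.step(lr_scale)
            losses.append(loss)
            step += 1
        history["loss"].append(float(np.mean(losses)))
        history["epoch_time_s"].append(time.time() - t0)

        if val_ws is not None and len(np.unique(val_ws.labels)) == 2:
            proba = model.predict_proba(val_ws.data)[:, 1]
            auroc = float(roc_auc_score(val_ws.labels, proba))
            history["val_auroc"].append(auroc)
            # >= breaks AUROC ties toward the later (better-calibrated) epoch
            if auroc >= best_auroc:
                best_auroc = auroc
                best_state = _snapshot(model)
        if verbose:
            msg = (f"epoch {epoch + 1}/{cfg.epochs} "
                   f"loss={history['loss'][-1]:.4f}")
            if history["val_auroc"]:
                msg += f" val_auroc={history['val_auroc'][-1]:.4f}"
            print(msg, flush=True)

    if best_state is not None:
        _restore(model, best_state)
    return model, history


def _snapshot(model: Model) -> list[np.ndarray]:
    return [m.params[k].copy() for m, k in model.parameters()]


def _restore(model: Model, state: list[np.ndarray]) -> None:
    for (m, k), v in zip(model.parameters(), state):
        m.params[k] = v.copy()


def predict_windows(model: Model, ws: WindowSet, batch_size: int = 256,
                    expected_len: int = 1250) -> np.ndarray:
    """Per-window (p_NSR, p_AFib) posteriors, in the window order of ``ws``.

    Windows must match the model's input contract (10 s at 125 Hz by default).
    """
    if ws.window_len != expected_len:
        raise ValueError(f"window length {ws.window_len} != {expected_len}")
    return model.predict_proba(ws.data, batch_size=batch_size)
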