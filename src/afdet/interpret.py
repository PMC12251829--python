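"""Guided Grad-CAM attribution over the input ECG time series.

Grad-CAM weights are the time-averaged gradients of the chosen class logit
with respect to the last-stage feature maps (temporal length 39 for a
1250-sample window with the default configuration); the class-activation map
is the rectified weighted sum of those features. Guided Grad-CAM multiplies
the CAM — linearly upsampled to input resolution — with guided-backpropagation
input gradients (the backward pass where activations pass a gradient only if
both the pre-activation and the gradient are positive; the same gate is
applied to GELU as to ReLU). Warm regions of the product mark samples that
push the model toward the target class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.models import Model

__all__ = ["Attribution", "gradcam", "guided_backprop", "guided_gradcam"]

CLASS_INDEX = {"NSR": 0, "AFIB": 1}


@dataclass(frozen=True)
class Attribution:
    """Per-sample relevance for one window and one target class."""

    values: np.ndarray       # (L,) guided Grad-CAM product
    cam: np.ndarray          # stage-resolution rectified CAM (before upsampling)
    guided: np.ndarray       # (L,) guided-backprop input gradients
    target_class: str


def _class_idx(target_class: int | str) -> int:
    if isinstance(target_class, str):
        try:
            return CLASS_INDEX[target_class.upper()]
        except KeyError:
            raise ValueError(f"unknown class {target_class!r}; "
                             f"expected NSR or AFIB") from None
    if target_class not in (0, 1):
        raise ValueError("class index must be 0 (NSR) or 1 (AFIB)")
    return int(target_class)


def _prep(window: np.ndarray) -> np.ndarray:
    w = np.asarray(window, dtype=np.float32)
    if w.ndim == 1:
        w = w[None, None, :]
    elif w.ndim == 2:
        w = w[None, :]
    return w


def gradcam(model: Model, window: np.ndarray,
            target_class: int | str = 1) -> np.ndarray:
    """Rectified class-activation map at last-stage temporal resolution."""
    c = _class_idx(target_class)
    x = _prep(window)
    model.zero_grad()
    feats = model.forward_features(x, train=True)      # (1, T4, C4)
    logits = model.head.forward(feats, train=True)
    done = np.zeros_like(logits)
    done[0, c] = 1.0
    dfeats = model.head.backward(done)                 # d logit_c / d feats
    weights = dfeats.mean(axis=1)                      # (1, C4) time-averaged
    cam = np.maximum((feats * weights[:, None, :]).sum(-1), 0.0)
    return cam[0]


def upsample_linear(cam: np.ndarray, length: int) -> np.ndarray:
    if len(cam) == 1:
        return np.full(length, float(cam[0]))
    src = np.linspace(0.0, 1.0, num=len(cam))
    dst = np.linspace(0.0, 1.0, num=length)
    return np.interp(dst, src, cam)


def guided_backprop(model: Model, window: np.ndarray,
                    target_class: int | str = 1) -> np.ndarray:
    """Guided-backpropagation gradient of the class logit w.r.t. the input."""
    c = _class_idx(target_class)
    x = _prep(window)
    model.zero_grad()
    logits = model.forward(x, train=True)
    done = np.zeros_like(logits)
    done[0, c] = 1.0
    dx = model.backward(done, guided=True)             # (1, C, L)
    return dx[0, 0]


def guided_gradcam(model: Model, window: np.ndarray,
                   target_class: int | str = 1) -> Attribution:
    """Elementwise product of the upsampled CAM with guided gradients."""
    c = _class_idx(target_class)
    cam = gradcam(model, window, c)
    guided = guided_backprop(model, window, c)
    values = upsample_linear(cam, len(guided)) * guided
    return Attribution(values=values, cam=cam, guided=guided,
                       target_class="AFIB" if c == 1 else "NSR")
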