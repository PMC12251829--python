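"""Training-time ECG window augmentation.

Seven stochastic transforms, each firing independently with its own
probability: amplitude scaling, amplitude offset, colored-noise infusion
(Gaussian / pink / brown), circular temporal shift, baseline wander,
amplitude negation (flip), and hard-negative replacement of non-AFib windows
by pure colored noise. Applied in a fixed order (scale, offset, shift,
wander, noise, flip, hard-noise) so a seeded generator reproduces a run
exactly. None of the transforms changes the window length or the label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AugmentConfig", "augment_window", "colored_noise", "baseline_wander"]

NOISE_COLORS = ("gaussian", "pink", "brown")


@dataclass(frozen=True)
class AugmentConfig:
    """Probabilities and ranges of the seven transforms.

    ``noise_scale_range`` is the noise standard deviation as a fraction of the
    window's own standard deviation (keeps the injected SNR comparable across
    records); ``offset_range`` is in signal units (mV).
    """

    p_scale: float = 0.75
    scale_range: tuple[float, float] = (0.6, 1.4)
    p_offset: float = 0.75
    offset_range: tuple[float, float] = (-0.2, 0.2)
    p_noise: float = 0.75
    noise_scale_range: tuple[float, float] = (0.0, 0.2)
    p_shift: float = 0.75
    shift_range_samples: tuple[int, int] = (-625, 625)
    p_wander: float = 0.25
    wander_amp: float = 0.3
    p_flip: float = 0.2
    p_hard_noise: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_scale", "p_offset", "p_noise", "p_shift",
                     "p_wander", "p_flip", "p_hard_noise"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.scale_range[0] <= 0:
            raise ValueError("scale_range must be positive")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(p_scale=0, p_offset=0, p_noise=0, p_shift=0,
                   p_wander=0, p_flip=0, p_hard_noise=0)


def colored_noise(n: int, color: str, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with flat (gaussian), 1/f (pink) or 1/f^2 (brown) PSD.

    Pink and brown are synthesized by shaping the spectrum of white noise by
    f^(-1/2) and f^(-1) respectively, then normalizing to zero mean and unit
    variance.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if color == "gaussian":
        x = rng.standard_normal(n)
    elif color in ("pink", "brown"):
        spec = np.fft.rfft(rng.standard_normal(n))
        f = np.fft.rfftfreq(n)
        f[0] = f[1]  # keep DC finite; removed by mean subtraction below
        spec *= f ** (-0.5 if color == "pink" else -1.0)
        x = np.fft.irfft(spec, n)
    else:
        raise ValueError(f"unknown noise color {color!r}; "
                         f"expected one of {NOISE_COLORS}")
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def baseline_wander(n: int, fs: float, rng: np.random.Generator,
                    max_amp: float = 0.3) -> np.ndarray:
    """Sum of 1-3 sub-0.5 Hz sinusoids with peak amplitude <= ``max_amp``."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n == 0:
        return np.empty(0)
    t = np.arange(n) / fs
    k = int(rng.integers(1, 4))
    w = np.zeros(n)
    for _ in range(k):
        freq = rng.uniform(0.05, 0.45)
        amp = rng.uniform(0.0, max_amp / 3.0)
        w += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return w


def augment_window(x: np.ndarray, y: int, cfg: AugmentConfig,
                   rng: np.random.Generator, fs: float = 125.0,
                   return_applied: bool = False):
    """Apply the augmentation suite to one window.

    Each transform fires independently with its configured probability;
    hard-noise replacement only applies to non-AFib windows (y=0) and
    replaces the window with colored noise at the window's own amplitude.
    Returns ``(x_aug, y)`` — the label never changes — and, when
    ``return_applied`` is set, a dict naming which transforms fired.
    """
    x = np.asarray(x, dtype=np.float64).copy()
    applied = {}

    applied["scale"] = rng.random() < cfg.p_scale
    if applied["scale"]:
        x *= rng.uniform(*cfg.scale_range)

    applied["offset"] = rng.random() < cfg.p_offset
    if applied["offset"]:
        x += rng.uniform(*cfg.offset_range)

    applied["shift"] = rng.random() < cfg.p_shift
    if applied["shift"]:
        lo, hi = cfg.shift_range_samples
        x = np.roll(x, int(rng.integers(lo, hi + 1)))

    applied["wander"] = rng.random() < cfg.p_wander
    if applied["wander"]:
        x += baseline_wander(len(x), fs, rng, cfg.wander_amp)

    applied["noise"] = rng.random() < cfg.p_noise
    if applied["noise"]:
        sd = rng.uniform(*cfg.noise_scale_range) * x.std()
        color = NOISE_COLORS[int(rng.integers(3))]
        x += sd * colored_noise(len(x), color, rng)

    applied["flip"] = rng.random() < cfg.p_flip
    if applied["flip"]:
        x = -x

    applied["hard_noise"] = rng.random() < cfg.p_hard_noise and y == 0
    if applied["hard_noise"]:
        color = NOISE_COLORS[int(rng.integers(3))]
        sd = x.std() or 1.0
        x = sd * colored_noise(len(x), color, rng)

    if return_applied:
        return x, y, applied
    return x, y
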