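"""ECG cleaning chain: zero-phase high-pass, powerline notch, resampling.

The chain applied to every record before windowing is

1. order-5 Butterworth high-pass at 0.5 Hz, run forward-backward so the
   composite filter has zero phase (no QRS latency shift),
2. a powerline notch (second-order IIR, Q=30, also forward-backward) at the
   configured mains frequency,
3. polyphase band-limited resampling to 125 Hz.

Filtering happens at the native rate, resampling last. Records shorter than
``min_samples`` after resampling (1250 samples, i.e. one 10 s window) are
excluded from windowing downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import AFIB, AFL, NOISE, NSR, OTHER, EcgRecord, RecordTooShortError

log = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig", "highpass", "powerline_filter", "resample_to",
    "standardize_diagnosis", "preprocess_record",
]


@dataclass(frozen=True)
class PreprocessConfig:
    hp_order: int = 5
    hp_cutoff_hz: float = 0.5
    mains_hz: float = 50.0          # 60 for North-American recordings
    notch_q: float = 30.0
    target_fs: float = 125.0
    min_samples: int = 1250

    def __post_init__(self) -> None:
        if not 0 < self.hp_cutoff_hz < self.target_fs / 2:
            raise ValueError("hp_cutoff_hz must lie in (0, target_fs/2)")


def highpass(x: np.ndarray, fs: float,
             cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Zero-phase order-``hp_order`` Butterworth high-pass at ``hp_cutoff_hz``.

    Applied forward-backward (``filtfilt``), so the effective magnitude
    response is the squared Butterworth magnitude and the group delay is zero.
    Removes DC and baseline drift below the cutoff.
    """
    if fs <= 1:
        raise ValueError("fs must exceed 1 Hz")
    x = np.asarray(x, dtype=np.float64)
    sos = sps.butter(cfg.hp_order, cfg.hp_cutoff_hz, btype="highpass",
                     fs=fs, output="sos")
    padlen = 3 * (2 * cfg.hp_order + 1)
    if len(x) <= padlen:
        raise RecordTooShortError(
            f"{len(x)} samples too short for forward-backward filtering")
    return sps.sosfiltfilt(sos, x)


def powerline_filter(x: np.ndarray, fs: float,
                     cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Suppress the mains tone with a zero-phase IIR notch (Q=``notch_q``).

    Skipped (with a warning) when the sampling rate cannot represent the
    mains frequency, i.e. ``fs <= 2 * mains_hz``.
    """
    x = np.asarray(x, dtype=np.float64)
    if fs <= 2 * cfg.mains_hz:
        log.warning("fs=%g Hz <= 2x mains (%g Hz); powerline filter skipped",
                    fs, cfg.mains_hz)
        return x
    b, a = sps.iirnotch(cfg.mains_hz, cfg.notch_q, fs=fs)
    padlen = 3 * max(len(a), len(b))
    if len(x) <= padlen:
        raise RecordTooShortError(
            f"{len(x)} samples too short for forward-backward filtering")
    return sps.filtfilt(b, a, x)


def resample_to(x: np.ndarray, fs_in: float, target_fs: float = 125.0) -> np.ndarray:
    """Polyphase band-limited resampling from ``fs_in`` to ``target_fs`` Hz.

    Output length is ``round(len(x) * target_fs / fs_in)``; the identity when
    the rates already match.
    """
    if fs_in <= 0:
        raise ValueError("fs_in must be positive")
    x = np.asarray(x, dtype=np.float64)
    if math.isclose(fs_in, target_fs):
        return x.copy()
    frac = Fraction(target_fs / fs_in).limit_denominator(1000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator)
    n_out = int(round(len(x) * target_fs / fs_in))
    if len(y) > n_out:
        y = y[:n_out]
    elif len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)), mode="edge")
    return y


# Dataset vocabularies differ; everything that is not AFib/AFL collapses onto
# OTHER (class 0), including the sinus variants named explicitly below.
_DIAGNOSIS_MAP = {
    "atrial fibrillation": AFIB, "afib": AFIB, "af": AFIB, "(afib": AFIB,
    "paroxysmal atrial fibrillation": AFIB, "164889003": AFIB,  # SNOMED AF
    "atrial flutter": AFL, "afl": AFL, "aflutter": AFL, "(afl": AFL,
    "164890007": AFL,  # SNOMED AFL
    "normal sinus rhythm": NSR, "sinus rhythm": NSR, "nsr": NSR, "sr": NSR,
    "(n": NSR, "normal": NSR, "426783006": NSR,  # SNOMED SR
    "sinus bradycardia": OTHER, "sinus tachycardia": OTHER,
    "sinus arrhythmia": OTHER,
    "noise": NOISE, "too noisy": NOISE,
}


def standardize_diagnosis(code: str, source: str = "") -> str:
    """Map a dataset-specific diagnosis code onto the canonical rhythm classes.

    Sinus bradycardia / tachycardia / arrhythmia map to OTHER (class 0);
    unknown codes map to OTHER with a logged warning.
    """
    key = code.strip().lower()
    if key in _DIAGNOSIS_MAP:
        return _DIAGNOSIS_MAP[key]
    log.warning("unknown diagnosis code %r (source=%r) -> OTHER", code, source)
    return OTHER


def preprocess_record(rec: EcgRecord,
                      cfg: PreprocessConfig = PreprocessConfig()) -> EcgRecord:
    """Apply the full cleaning chain to every lead and resample to target_fs.

    Raises :class:`RecordTooShortError` when the resampled record would fall
    below ``cfg.min_samples`` (the 1250-sample exclusion rule).
    """
    n_out = int(round(rec.n_samples * cfg.target_fs / rec.fs))
    if n_out < cfg.min_samples:
        raise RecordTooShortError(
            f"record {rec.record_id!r}: {n_out} samples at "
            f"{cfg.target_fs:g} Hz < {cfg.min_samples}")
    leads = []
    for ch in range(rec.signal.shape[0]):
        x = highpass(rec.lead(ch), rec.fs, cfg)
        x = powerline_filter(x, rec.fs, cfg)
        leads.append(resample_to(x, rec.fs, cfg.target_fs))
    # rhythm times are in seconds and therefore survive resampling unchanged
    return EcgRecord(record_id=rec.record_id, signal=np.vstack(leads),
                     fs=cfg.target_fs, lead_names=list(rec.lead_names),
                     rhythms=list(rec.rhythms))
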