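"""ECG record I/O: WFDB records and annotations, windowing, HDF5 window sets.

The on-disk formats handled here are the PhysioNet WFDB conventions used by
the MIT-BIH family of databases (text ``.hea`` headers, binary ``.dat``
signals in format 16 or 212, ``.atr`` annotation files whose rhythm changes
are marked with ``+`` annotations carrying aux strings like ``(AFIB``) and a
simple HDF5 container holding an N×C×L float32 tensor of fixed-length ECG
windows with binary labels.

All intervals are half-open ``[start_s, end_s)`` in seconds, 0-based; sample
``i`` covers time ``[i/fs, (i+1)/fs)``.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np

__all__ = [
    "AFIB", "AFL", "NSR", "OTHER", "NOISE",
    "EpisodeLabel", "EcgRecord", "WindowSet",
    "FormatError", "LeadError", "RecordTooShortError",
    "read_wfdb_record", "write_wfdb_record",
    "read_annotations", "write_annotations",
    "rhythm_stream_to_intervals", "extract_windows",
    "write_hdf5", "read_hdf5", "open_hdf5_lazy",
]

# canonical rhythm classes; AFIB and AFL (and only those) form the positive class
AFIB = "AFIB"
AFL = "AFL"
NSR = "NSR"
OTHER = "OTHER"
NOISE = "NOISE"

POSITIVE_LABELS = frozenset({AFIB, AFL})

#: WFDB rhythm aux strings -> canonical class
RHYTHM_AUX_MAP = {
    "(AFIB": AFIB,
    "(AFL": AFL,
    "(N": NSR,
    "(NSR": NSR,
    "(SR": NSR,
    "(NOISE": NOISE,
}


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class LeadError(KeyError):
    """A requested lead is not present in the record."""


class RecordTooShortError(ValueError):
    """Record shorter than the minimum usable length (1250 samples at 125 Hz)."""


@dataclass(frozen=True)
class EpisodeLabel:
    """A labelled rhythm interval ``[start_s, end_s)`` in seconds."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"empty episode [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EcgRecord:
    """A multi-channel ECG signal in millivolts with ground-truth rhythms."""

    record_id: str
    signal: np.ndarray          # (channels, samples), mV
    fs: float                   # Hz
    lead_names: list[str] = field(default_factory=list)
    rhythms: list[EpisodeLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signal.shape[1] < 1:
            raise ValueError("record must contain at least one sample")
        if not self.lead_names:
            self.lead_names = [f"lead{i}" for i in range(self.signal.shape[0])]
        dur = self.duration_s
        for ep in self.rhythms:
            if ep.start_s < -1e-9 or ep.end_s > dur + 1e-9:
                raise ValueError(f"rhythm {ep} outside record [0, {dur})")
        self.rhythms = sorted(self.rhythms, key=lambda e: e.start_s)
        for a, b in zip(self.rhythms, self.rhythms[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(f"overlapping rhythm intervals {a} / {b}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, selector: int | str = 0) -> np.ndarray:
        """Return one lead as a 1-D array; selector is an index or lead name."""
        if isinstance(selector, str):
            try:
                selector = self.lead_names.index(selector)
            except ValueError:
                raise LeadError(f"lead {selector!r} not in {self.lead_names}") from None
        if not 0 <= selector < self.signal.shape[0]:
            raise LeadError(f"lead index {selector} out of range")
        return self.signal[selector]


@dataclass
class WindowSet:
    """Fixed-length ECG windows as an N×C×L tensor with binary labels.

    ``labels[i] == 1`` marks a window dominated by AFib/AFL; provenance is kept
    per window as ``(record_id, start_s)``.
    """

    data: np.ndarray            # (N, 1, L) float32
    labels: np.ndarray          # (N,) int8 in {0, 1}
    fs: float = 125.0
    window_len_s: float = 10.0
    record_ids: list[str] = field(default_factory=list)
    start_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("data must be N x C x L")
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.labels) != len(self.data):
            raise ValueError("labels length mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        L = self.data.shape[2]
        if abs(L - self.window_len_s * self.fs) > 1e-6:
            raise ValueError(f"L={L} != window_len_s*fs={self.window_len_s * self.fs}")
        if not self.record_ids:
            self.record_ids = [""] * len(self.data)
        if self.start_s.size == 0:
            self.start_s = np.zeros(len(self.data))
        self.start_s = np.asarray(self.start_s, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def window_len(self) -> int:
        return self.data.shape[2]

    @staticmethod
    def concatenate(sets: Sequence["WindowSet"]) -> "WindowSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        first = sets[0]
        return WindowSet(
            data=np.concatenate([s.data for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            fs=first.fs,
            window_len_s=first.window_len_s,
            record_ids=[r for s in sets for r in s.record_ids],
            start_s=np.concatenate([s.start_s for s in sets]),
        )

    def subset(self, idx: np.ndarray) -> "WindowSet":
        idx = np.asarray(idx)
        return WindowSet(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            window_len_s=self.window_len_s,
            record_ids=[self.record_ids[i] for i in np.atleast_1d(idx)],
            start_s=self.start_s[idx],
        )


# ---------------------------------------------------------------------------
# WFDB signal files
# ---------------------------------------------------------------------------

def _parse_gain_field(tok: str) -> tuple[float, int, str]:
    """Parse a header gain token ``gain(baseline)/units`` with WFDB defaults."""
    units = "mV"
    if "/" in tok:
        tok, units = tok.split("/", 1)
    baseline = None
    if "(" in tok:
        tok, rest = tok.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(tok) if tok else 0.0
    if gain == 0.0:
        gain = 200.0  # WFDB default ADC gain
    return gain, (0 if baseline is None else baseline), units


def read_wfdb_record(path: str | os.PathLike,
                     channel: int | str | None = None) -> EcgRecord:
    """Read a WFDB record (``.hea`` + ``.dat`` [+ ``.atr``]) from ``path``.

    ``path`` is the record path without extension. ``channel`` optionally
    restricts the returned record to a single lead (index or name); by default
    all leads are returned. Signal formats 16 and 212 are supported, which
    covers the MIT-BIH style databases.
    """
    path = os.fspath(path)
    hea = path + ".hea"
    if not os.path.exists(hea):
        raise FormatError(f"missing header file {hea}")
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    try:
        head = lines[0].split()
        record_name = head[0].split("/")[0]
        nsig = int(head[1])
        fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
        nsamp = int(head[3]) if len(head) > 3 else 0
    except (IndexError, ValueError) as exc:
        raise FormatError(f"corrupt header {hea}: {exc}") from exc

    sig_lines = lines[1:1 + nsig]
    if len(sig_lines) < nsig:
        raise FormatError(f"header {hea} declares {nsig} signals, "
                          f"found {len(sig_lines)} signal lines")
    files, fmts, gains, baselines, names = [], [], [], [], []
    for i, ln in enumerate(sig_lines):
        toks = ln.split()
        if len(toks) < 2:
            raise FormatError(f"corrupt signal line in {hea}: {ln!r}")
        files.append(toks[0])
        fmts.append(toks[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, _units = _parse_gain_field(toks[2]) if len(toks) > 2 \
            else (200.0, 0, "mV")
        # explicit ADC zero (field 5) overrides an absent baseline
        if len(toks) > 4 and "(" not in (toks[2] if len(toks) > 2 else ""):
            try:
                baseline = int(toks[4])
            except ValueError:
                pass
        gains.append(gain)
        baselines.append(baseline)
        names.append(toks[8] if len(toks) > 8 else f"lead{i}")

    if len(set(files)) != 1:
        raise FormatError("multi-file records are not supported")
    if len(set(fmts)) != 1:
        raise FormatError("mixed signal formats are not supported")
    fmt = fmts[0]
    dat = os.path.join(os.path.dirname(path), files[0])
    if not os.path.exists(dat):
        raise FormatError(f"missing signal file {dat}")
    raw = np.fromfile(dat, dtype=np.uint8)

    if fmt == "16":
        adc = raw.view("<i2").astype(np.int32)
        adc = adc[: (len(adc) // nsig) * nsig].reshape(-1, nsig).T
    elif fmt == "212":
        adc = _decode_fmt212(raw)
        adc = adc[: (len(adc) // nsig) * nsig].reshape(-1, nsig).T
    else:
        raise FormatError(f"unsupported WFDB signal format {fmt!r}")
    if nsamp:
        adc = adc[:, :nsamp]

    phys = (adc - np.array(baselines)[:, None]) / np.array(gains)[:, None]

    rhythms: list[EpisodeLabel] = []
    atr = path + ".atr"
    if os.path.exists(atr):
        events = [(t / fs, aux) for t, code, aux in read_annotations(atr)
                  if aux.startswith("(")]
        if events:
            rhythms = rhythm_stream_to_intervals(events, adc.shape[1] / fs)

    rec = EcgRecord(record_id=record_name, signal=phys, fs=fs,
                    lead_names=names, rhythms=rhythms)
    if channel is not None:
        idx = (rec.lead_names.index(channel) if isinstance(channel, str)
               and channel in rec.lead_names else channel)
        lead = rec.lead(idx)  # raises LeadError when absent
        name = rec.lead_names[rec.lead_names.index(channel)] \
            if isinstance(channel, str) else rec.lead_names[int(idx)]
        rec = EcgRecord(record_id=rec.record_id, signal=lead[None, :],
                        fs=fs, lead_names=[name], rhythms=rhythms)
    return rec


def _decode_fmt212(raw: np.ndarray) -> np.ndarray:
    """Unpack WFDB format 212 (two 12-bit samples in three bytes)."""
    n3 = (len(raw) // 3) * 3
    b = raw[:n3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * len(b), dtype=np.int32)
    out[0::2], out[1::2] = s0, s1
    out[out > 2047] -= 4096  # 12-bit two's complement
    return out


def write_wfdb_record(rec: EcgRecord, path: str | os.PathLike,
                      gain: float = 200.0) -> None:
    """Write ``rec`` as a WFDB format-16 record (and ``.atr`` if it has rhythms)."""
    path = os.fspath(path)
    base = os.path.basename(path)
    adc = np.clip(np.round(rec.signal * gain), -32768, 32767).astype("<i2")
    with open(path + ".hea", "w") as fh:
        fh.write(f"{base} {adc.shape[0]} {rec.fs:g} {adc.shape[1]}\n")
        for name in rec.lead_names:
            fh.write(f"{base}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 {name}\n")
    adc.T.tofile(path + ".dat")
    if rec.rhythms:
        anns = [(int(round(ep.start_s * rec.fs)), 28, _label_to_aux(ep.label))
                for ep in rec.rhythms]
        write_annotations(anns, path + ".atr")


def _label_to_aux(label: str) -> str:
    for aux, lab in RHYTHM_AUX_MAP.items():
        if lab == label and aux not in ("(NSR", "(SR"):
            return aux
    return "(" + label


# ---------------------------------------------------------------------------
# WFDB annotation files (MIT format)
# ---------------------------------------------------------------------------

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def read_annotations(path: str | os.PathLike) -> list[tuple[int, int, str]]:
    """Read an MIT-format annotation file as ``(sample, code, aux)`` tuples."""
    raw = np.fromfile(os.fspath(path), dtype=np.uint8)
    out: list[tuple[int, int, str]] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(raw):
        word = int(raw[i]) | (int(raw[i + 1]) << 8)
        i += 2
        code = word >> 10
        tfield = word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            if i + 3 >= len(raw):
                raise FormatError(f"truncated SKIP in {path}")
            hi = int(raw[i]) | (int(raw[i + 1]) << 8)
            lo = int(raw[i + 2]) | (int(raw[i + 3]) << 8)
            i += 4
            pending_skip = struct.unpack("<i", struct.pack("<I", (hi << 16) | lo))[0]
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            aux = bytes(raw[i:i + tfield]).rstrip(b"\x00").decode("ascii", "replace")
            i += tfield + (tfield & 1)  # pad to even
            if out:
                s, c, _ = out[-1]
                out[-1] = (s, c, aux)
        else:
            t += tfield + pending_skip
            pending_skip = 0
            out.append((t, code, ""))
    return out


def write_annotations(anns: Iterable[tuple[int, int, str]],
                      path: str | os.PathLike) -> None:
    """Write ``(sample, code, aux)`` annotations in MIT format."""
    buf = bytearray()
    prev = 0
    for sample, code, aux in sorted(anns):
        dt = sample - prev
        prev = sample
        if dt > 1023 or dt < 0:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<H", (dt >> 16) & 0xFFFF)
            buf += struct.pack("<H", dt & 0xFFFF)
            dt = 0
        buf += struct.pack("<H", (code << 10) | dt)
        if aux:
            data = aux.encode("ascii")
            buf += struct.pack("<H", (_AUX << 10) | len(data))
            buf += data
            if len(data) & 1:
                buf += b"\x00"
    buf += struct.pack("<H", 0)
    with open(os.fspath(path), "wb") as fh:
        fh.write(bytes(buf))


# ---------------------------------------------------------------------------
# Rhythm streams and window extraction
# ---------------------------------------------------------------------------

def standardize_rhythm_code(code: str) -> str:
    """Map a WFDB rhythm aux string onto the canonical five rhythm classes."""
    code = code.strip()
    if code in RHYTHM_AUX_MAP:
        return RHYTHM_AUX_MAP[code]
    return OTHER


def rhythm_stream_to_intervals(events: Sequence[tuple[float, str]],
                               record_end_s: float) -> list[EpisodeLabel]:
    """Turn a stream of (time_s, rhythm_code) change events into intervals.

    Each event opens an interval that the next event (or the record end)
    closes, so the intervals tile ``[first event, record_end_s)``.
    """
    if not events:
        return []
    times = [t for t, _ in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("rhythm events must be sorted by time")
    out: list[EpisodeLabel] = []
    for (t0, code), t1 in zip(events, times[1:] + [record_end_s]):
        if t1 > t0:  # zero-length intervals (simultaneous events) are dropped
            out.append(EpisodeLabel(t0, min(t1, record_end_s),
                                    standardize_rhythm_code(code)))
    return out


def positive_overlap_fraction(rec: EcgRecord, start_s: float,
                              end_s: float) -> float:
    """Fraction of ``[start_s, end_s)`` covered by AFib/AFL rhythm intervals."""
    cover = 0.0
    for ep in rec.rhythms:
        if ep.label in POSITIVE_LABELS:
            cover += max(0.0, min(ep.end_s, end_s) - max(ep.start_s, start_s))
    return cover / (end_s - start_s)


def extract_windows(rec: EcgRecord, window_len_s: float = 10.0,
                    label_fraction: float = 0.5,
                    channel: int | str = 0) -> WindowSet:
    """Cut a record into non-overlapping windows with binary AFib/AFL labels.

    A window is labelled 1 when at least ``label_fraction`` of its duration
    overlaps AFib/AFL intervals (``label_fraction=0`` means any overlap).
    The trailing partial window is discarded; a record shorter than one
    window raises :class:`RecordTooShortError` (the exclusion rule for
    records under 1250 samples at 125 Hz).
    """
    L = window_len_s * rec.fs
    if abs(L - round(L)) > 1e-9:
        raise ValueError("window_len_s * fs must be an integer sample count")
    L = int(round(L))
    x = rec.lead(channel)
    n = len(x) // L
    if n == 0:
        raise RecordTooShortError(
            f"record {rec.record_id!r} has {len(x)} samples < {L}")
    data = x[: n * L].reshape(n, 1, L).astype(np.float32)
    labels = np.zeros(n, dtype=np.int8)
    for i in range(n):
        frac = positive_overlap_fraction(rec, i * window_len_s,
                                         (i + 1) * window_len_s)
        if (frac > 0.0) if label_fraction == 0.0 else (frac >= label_fraction):
            labels[i] = 1
    return WindowSet(
        data=data, labels=labels, fs=rec.fs, window_len_s=window_len_s,
        record_ids=[rec.record_id] * n,
        start_s=np.arange(n) * float(window_len_s),
    )


# ---------------------------------------------------------------------------
# HDF5 window container
# ---------------------------------------------------------------------------

def write_hdf5(ws: WindowSet, path: str | os.PathLike) -> None:
    """Write a :class:`WindowSet` as an HDF5 file (N×C×L float32 + labels)."""
    with h5py.File(os.fspath(path), "w") as f:
        # track_times=False keeps files byte-identical across identical runs
        f.create_dataset("windows", data=ws.data, dtype="f4", track_times=False)
        f.create_dataset("labels", data=ws.labels, dtype="i1", track_times=False)
        f.create_dataset("record_id",
                         data=np.array(ws.record_ids, dtype=h5py.string_dtype()),
                         track_times=False)
        f.create_dataset("start_s", data=ws.start_s, dtype="f8",
                         track_times=False)
        f.attrs["fs"] = ws.fs
        f.attrs["window_len_s"] = ws.window_len_s


def read_hdf5(path: str | os.PathLike) -> WindowSet:
    with h5py.File(os.fspath(path), "r") as f:
        _check_layout(f)
        return WindowSet(
            data=f["windows"][...],
            labels=f["labels"][...],
            fs=float(f.attrs["fs"]),
            window_len_s=float(f.attrs["window_len_s"]),
            record_ids=[s.decode() if isinstance(s, bytes) else str(s)
                        for s in f["record_id"][...]],
            start_s=f["start_s"][...],
        )


def _check_layout(f: h5py.File) -> None:
    for name in ("windows", "labels"):
        if name not in f:
            raise FormatError(f"HDF5 file lacks dataset {name!r}")
    if f["windows"].ndim != 3:
        raise FormatError("'windows' dataset must be N x C x L")
    if len(f["labels"]) != len(f["windows"]):
        raise FormatError("'labels' length does not match 'windows'")


def open_hdf5_lazy(path: str | os.PathLike,
                   batch_size: int) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Iterate over an HDF5 window file in batches without loading it whole.

    Yields ``(windows, labels)`` pairs of at most ``batch_size`` windows;
    only one batch is resident in memory at a time.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    with h5py.File(os.fspath(path), "r") as f:
        _check_layout(f)
        n = len(f["windows"])
        for lo in range(0, n, batch_size):
            hi = min(lo + batch_size, n)
            yield f["windows"][lo:hi], f["labels"][lo:hi]
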