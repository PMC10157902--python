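"""Minimal European Data Format (EDF) reader/writer.

Supports the subset needed here: continuous multichannel recordings, one
physical unit (µV), equal sampling rate on every channel, 1-second data
records, 16-bit little-endian samples.  No annotations (events travel in a
sidecar TSV).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

__all__ = ["write_edf", "read_edf"]

_HEADER_FIXED = 256
_PER_SIGNAL = 256

# physical range chosen so the 16-bit resolution is 0.1 µV
_PHYS_MIN = -3276.8
_PHYS_MAX = 3276.8
_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    samples: np.ndarray,
    fs: float,
    channel_labels,
    patient: str = "X",
    recording: str = "X",
) -> None:
    """Write ``samples`` (channels x time, µV) to an EDF file.

    The number of samples must be an integer multiple of ``fs`` (whole
    1-second records); the synthetic generator always satisfies this.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be a 2-D channels x time array")
    n_ch, n_samp = samples.shape
    if len(channel_labels) != n_ch:
        raise ValueError("channel_labels length mismatch")
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("write_edf requires an integer sampling rate")
    if n_samp % spr != 0:
        raise ValueError(
            f"recording length {n_samp} is not a whole number of 1 s records at fs={fs}"
        )
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples contain non-finite values")
    if samples.min() < _PHYS_MIN or samples.max() > _PHYS_MAX:
        raise ValueError("samples exceed the representable physical range (±3276.8 µV)")
    n_records = n_samp // spr

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field(patient, 80),
            _field(recording, 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(_HEADER_FIXED + _PER_SIGNAL * n_ch, 8),
            _field("", 44),
            _field(n_records, 8),
            _field("1", 8),
            _field(n_ch, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(lab, 16) for lab in channel_labels),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(_PHYS_MIN, 8) for _ in range(n_ch)),
            b"".join(_field(_PHYS_MAX, 8) for _ in range(n_ch)),
            b"".join(_field(_DIG_MIN, 8) for _ in range(n_ch)),
            b"".join(_field(_DIG_MAX, 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(spr, 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )

    scale = (_PHYS_MAX - _PHYS_MIN) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((samples - _PHYS_MIN) / scale).astype(np.int64) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    # records: for each 1 s record, all samples of signal 0, then signal 1, ...
    rec = digital.reshape(n_ch, n_records, spr).transpose(1, 0, 2)
    Path(path).write_bytes(header + sig + rec.tobytes())


def read_edf(path):
    """Read an EDF file written by :func:`write_edf` (or compatible).

    Returns ``(samples, fs, channel_labels)`` with samples in physical units.
    """
    buf = Path(path).read_bytes()
    if len(buf) < _HEADER_FIXED:
        raise ValueError("not an EDF file (truncated header)")

    def f(off, width):
        return buf[off : off + width].decode("ascii", errors="replace").strip()

    n_records = int(f(236, 8))
    record_dur = float(f(244, 8))
    n_ch = int(f(252, 4))
    base = _HEADER_FIXED

    def sig_fields(off, width):
        start = base + off * n_ch
        return [
            buf[start + i * width : start + (i + 1) * width].decode("ascii").strip()
            for i in range(n_ch)
        ]

    # per-signal block offsets in bytes-per-field units
    labels = sig_fields(0, 16)
    phys_min = np.array([float(v) for v in sig_fields(16 + 80 + 8, 8)])
    phys_max = np.array([float(v) for v in sig_fields(16 + 80 + 8 + 8, 8)])
    dig_min = np.array([float(v) for v in sig_fields(16 + 80 + 8 + 16, 8)])
    dig_max = np.array([float(v) for v in sig_fields(16 + 80 + 8 + 24, 8)])
    spr = [int(v) for v in sig_fields(16 + 80 + 8 + 32 + 80, 8)]
    if len(set(spr)) != 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    spr = spr[0]
    fs = spr / record_dur

    data_off = _HEADER_FIXED + _PER_SIGNAL * n_ch
    raw = np.frombuffer(buf, dtype="<i2", offset=data_off, count=n_records * n_ch * spr)
    rec = raw.reshape(n_records, n_ch, spr).transpose(1, 0, 2).reshape(n_ch, -1)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    samples = (rec.astype(float) - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    return samples, fs, labels
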