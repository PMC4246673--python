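"""Minimal EDF (European Data Format) writer for ECoG exports.

Implements the plain EDF variant: an ASCII header followed by 2-byte
little-endian integer samples, one data record per second.  Signals are
scaled channel-wise from their physical range onto the full 16-bit digital
range.  Only writing is provided; any EDF-capable reader (e.g. MNE) can
load the result.
"""

from __future__ import annotations

import datetime

import numpy as np

_DIGITAL_MIN, _DIGITAL_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, sample_rate: float,
              channel_labels=None, physical_dim: str = "mV",
              start: datetime.datetime | None = None) -> None:
    """Write ``data`` (n_samples, n_channels) as an EDF file.

    The recording is chopped into 1 s data records; a trailing partial
    second is dropped.  Physical ranges are per-channel min/max (widened
    slightly so extreme samples stay representable).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < data.shape[1]:
        raise ValueError("data must be (n_samples, n_channels)")
    n_samples, n_ch = data.shape
    spr = int(round(sample_rate))            # samples per 1 s record
    n_records = n_samples // spr
    if n_records < 1:
        raise ValueError("need at least one full second of data")
    if channel_labels is None:
        channel_labels = [f"ch{i + 1}" for i in range(n_ch)]
    if len(channel_labels) != n_ch:
        raise ValueError("one label per channel required")
    start = start or datetime.datetime(2000, 1, 1, 0, 0, 0)

    phys_min = data.min(axis=0)
    phys_max = data.max(axis=0)
    span = np.maximum(phys_max - phys_min, 1e-6)
    phys_min = phys_min - 0.01 * span
    phys_max = phys_max + 0.01 * span

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),                       # local patient id
        _field("Startdate X X X X", 80),             # local recording id
        _field(start.strftime("%d.%m.%y"), 8),
        _field(start.strftime("%H.%M.%S"), 8),
        _field(256 * (n_ch + 1), 8),                 # header byte count
        _field("", 44),
        _field(n_records, 8),
        _field("1", 8),                              # record duration, s
        _field(n_ch, 4),
    ])
    per_signal = b"".join([
        b"".join(_field(lab, 16) for lab in channel_labels),
        b"".join(_field("", 80) for _ in range(n_ch)),       # transducer
        b"".join(_field(physical_dim, 8) for _ in range(n_ch)),
        b"".join(_field(f"{v:.6g}", 8) for v in phys_min),
        b"".join(_field(f"{v:.6g}", 8) for v in phys_max),
        b"".join(_field(_DIGITAL_MIN, 8) for _ in range(n_ch)),
        b"".join(_field(_DIGITAL_MAX, 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),       # prefiltering
        b"".join(_field(spr, 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ])

    gain = (_DIGITAL_MAX - _DIGITAL_MIN) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * gain + _DIGITAL_MIN)
    digital = np.clip(digital, _DIGITAL_MIN, _DIGITAL_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        for rec in range(n_records):
            chunk = digital[rec * spr:(rec + 1) * spr]   # (spr, n_ch)
            fh.write(chunk.T.tobytes())                  # channel-major
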