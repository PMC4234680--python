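"""Minimal EDF (European Data Format) reader/writer for oximetry channels.

Supports the plain EDF profile this package needs: a fixed ASCII header,
int16 little-endian data records, and per-channel physical/digital
scaling.  The record duration is chosen so every channel has an integer
number of samples per record (2 s for the 1 Hz + 62.5 Hz pair).  SpO2 is
scaled so that one digital unit equals the 0.1% resolution step, making
write -> read round-trips exact for quantized saturation values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import OxiscreenError


class EDFError(OxiscreenError):
    """Malformed or unsupported EDF content."""


@dataclass
class EDFChannel:
    label: str
    data: np.ndarray
    fs: float
    physical_dim: str = ""
    physical_min: float | None = None   # None -> from data (symmetric)
    physical_max: float | None = None
    digital_min: int = -32768
    digital_max: int = 32767


def _record_duration(rates: list[float]) -> int:
    """Smallest integer record duration giving whole samples per record."""
    for d in range(1, 61):
        if all(abs(r * d - round(r * d)) < 1e-9 for r in rates):
            return d
    raise EDFError(f"no integer record duration <= 60 s for rates {rates}")


def _field(value: str, width: int) -> bytes:
    s = value[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, channels: list[EDFChannel]) -> None:
    """Write channels to a plain EDF file (truncating to whole records)."""
    if not channels:
        raise EDFError("no channels to write")
    dur = _record_duration([c.fs for c in channels])
    n_records = min(int(math.floor(c.data.size / (c.fs * dur))) for c in channels)
    if n_records < 1:
        raise EDFError("channels shorter than one data record")
    ns = len(channels)

    scaled: list[np.ndarray] = []
    phys: list[tuple[float, float]] = []
    for c in channels:
        x = np.asarray(c.data, dtype=float)[: int(c.fs * dur) * n_records]
        if c.physical_min is not None and c.physical_max is not None:
            pmin, pmax = float(c.physical_min), float(c.physical_max)
        else:
            amp = float(np.max(np.abs(x))) or 1.0
            pmin, pmax = -amp, amp
        gain = (pmax - pmin) / (c.digital_max - c.digital_min)
        dig = np.round((x - pmin) / gain) + c.digital_min
        if dig.min() < c.digital_min or dig.max() > c.digital_max:
            raise EDFError(f"channel {c.label}: data exceeds physical range")
        scaled.append(dig.astype("<i2"))
        phys.append((pmin, pmax))

    header = b"".join([
        _field("0", 8),
        _field("oxiscreen", 80),
        _field("synthetic or converted oximetry", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (ns + 1)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field(str(dur), 8),
        _field(str(ns), 4),
    ])
    for w, get in [
        (16, lambda c, i: c.label),
        (80, lambda c, i: ""),
        (8, lambda c, i: c.physical_dim),
        (8, lambda c, i: f"{phys[i][0]:.8g}"[:8]),
        (8, lambda c, i: f"{phys[i][1]:.8g}"[:8]),
        (8, lambda c, i: str(c.digital_min)),
        (8, lambda c, i: str(c.digital_max)),
        (80, lambda c, i: ""),
        (8, lambda c, i: str(int(c.fs * dur))),
        (32, lambda c, i: ""),
    ]:
        header += b"".join(_field(get(c, i), w) for i, c in enumerate(channels))

    spr = [int(c.fs * dur) for c in channels]
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for i in range(ns):
                fh.write(scaled[i][r * spr[i] : (r + 1) * spr[i]].tobytes())


def read_edf(path: str | Path) -> dict[str, tuple[np.ndarray, float]]:
    """Read a plain EDF file; returns {label: (values, sampling_rate)}."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise EDFError("file too short for an EDF header")

    def ascii_at(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    try:
        n_records = int(ascii_at(236, 8))
        dur = float(ascii_at(244, 8))
        ns = int(ascii_at(252, 4))
    except ValueError as exc:
        raise EDFError(f"malformed EDF header: {exc}") from exc
    off = 256

    def sig_fields(width: int) -> list[str]:
        nonlocal off
        vals = [ascii_at(off + i * width, width) for i in range(ns)]
        off += width * ns
        return vals

    labels = sig_fields(16)
    sig_fields(80)                      # transducer
    sig_fields(8)                       # physical dimension
    pmins = [float(v) for v in sig_fields(8)]
    pmaxs = [float(v) for v in sig_fields(8)]
    dmins = [int(v) for v in sig_fields(8)]
    dmaxs = [int(v) for v in sig_fields(8)]
    sig_fields(80)                      # prefiltering
    spr = [int(v) for v in sig_fields(8)]
    sig_fields(32)                      # reserved

    data_off = 256 * (ns + 1)
    rec_len = sum(spr)
    body = np.frombuffer(raw, dtype="<i2", offset=data_off)
    if body.size < n_records * rec_len:
        raise EDFError("EDF data shorter than header declares")
    body = body[: n_records * rec_len].reshape(n_records, rec_len)
    out: dict[str, tuple[np.ndarray, float]] = {}
    pos = 0
    for i in range(ns):
        dig = body[:, pos : pos + spr[i]].reshape(-1).astype(float)
        pos += spr[i]
        # multiply before dividing: for integer-valued spans this yields the
        # correctly rounded decimal (e.g. (843*100)/1000 == 84.3 exactly)
        vals = pmins[i] + (dig - dmins[i]) * (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        out[labels[i]] = (vals, spr[i] / dur)
    return out
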