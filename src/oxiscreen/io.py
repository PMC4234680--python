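"""File I/O: recordings (long-form CSV, EDF) and feature tables (CSV).

CSV recordings are long-form for transparency: columns ``time_s``,
``channel``, ``value``, one row per sample, channels ``SpO2`` and ``PPG``
(``Pleth`` is accepted as a PPG alias).  Sampling rates are established
from the time column and validated for uniformity.  Feature tables are
one row per subject with full-precision (repr) floats, so write -> read
round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import edf
from .aggregate import SubjectFeatureVector, vectors_to_frame
from .model import (
    ChannelMissingError,
    InconsistentSamplingError,
    OximetryRecording,
    OxiscreenError,
    UNKNOWN,
)

SPO2_LABELS = ("SpO2", "SPO2", "spo2")
PPG_LABELS = ("PPG", "Pleth", "ppg", "pleth")


def _infer_fs(times: np.ndarray, channel: str) -> float:
    dt = np.diff(times)
    if dt.size == 0 or np.any(dt <= 0):
        raise InconsistentSamplingError(f"channel {channel}: non-increasing time column")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise InconsistentSamplingError(
            f"channel {channel}: sampling interval varies beyond 1% of {med:.6g} s"
        )
    return 1.0 / med


def _pick(channels: dict[str, tuple[np.ndarray, float]], names: tuple[str, ...],
          what: str) -> tuple[np.ndarray, float]:
    for name in names:
        if name in channels:
            return channels[name]
    raise ChannelMissingError(
        f"{what} channel not found: expected one of {names}, file has {sorted(channels)}"
    )


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    subject_id: str | None = None,
    ahi: float | None = None,
    ahi_threshold: float = 5.0,
) -> OximetryRecording:
    """Read a two-channel recording from CSV (long form) or EDF.

    Out-of-range SpO2 samples are retained (they are flagged by the
    cleaning stage, not dropped at read time).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"time_s", "channel", "value"}
        if not required.issubset(df.columns):
            raise OxiscreenError(
                f"CSV must have columns {sorted(required)}, found {list(df.columns)}"
            )
        channels = {}
        for name, grp in df.groupby("channel"):
            t = grp["time_s"].to_numpy(dtype=float)
            v = grp["value"].to_numpy(dtype=float)
            channels[str(name)] = (v, _infer_fs(t, str(name)))
    elif fmt == "edf":
        channels = edf.read_edf(path)
    else:
        raise OxiscreenError(f"unknown recording format: {fmt!r} (expected csv or edf)")
    spo2, spo2_fs = _pick(channels, SPO2_LABELS, "SpO2")
    ppg, ppg_fs = _pick(channels, PPG_LABELS, "PPG")
    return OximetryRecording(
        subject_id=subject_id or path.stem,
        spo2=spo2, ppg=ppg, spo2_fs=spo2_fs, ppg_fs=ppg_fs,
        ahi=ahi, ahi_threshold=ahi_threshold,
    )


def write_recording_csv(rec: OximetryRecording, path: str | Path) -> None:
    """Write a recording as long-form CSV (full-precision floats)."""
    t_spo2 = np.arange(rec.spo2.size) / rec.spo2_fs
    t_ppg = np.arange(rec.ppg.size) / rec.ppg_fs
    df = pd.DataFrame({
        "time_s": np.concatenate([t_spo2, t_ppg]),
        "channel": ["SpO2"] * rec.spo2.size + ["PPG"] * rec.ppg.size,
        "value": np.concatenate([rec.spo2, rec.ppg]),
    })
    df.to_csv(path, index=False)


def write_recording_edf(rec: OximetryRecording, path: str | Path) -> None:
    """Write a recording as plain EDF (SpO2 scaled to exact 0.1% steps)."""
    # one digital unit == one resolution step; dig_max chosen so the gain
    # (phys_max - phys_min)/(dig_max - dig_min) is exactly the resolution
    res = rec.spo2_resolution
    dig_max = int(round(100.0 / res))
    channels = [
        edf.EDFChannel(
            "SpO2", rec.spo2, rec.spo2_fs, physical_dim="%",
            physical_min=0.0, physical_max=100.0,
            digital_min=0, digital_max=dig_max,
        ),
        edf.EDFChannel("PPG", rec.ppg, rec.ppg_fs, physical_dim="au"),
    ]
    edf.write_edf(path, channels)


def write_feature_table(
    vectors: list[SubjectFeatureVector] | pd.DataFrame, path: str | Path
) -> None:
    """One row per subject; columns follow the M_/Me_/S_/I_ naming.

    Feature names are already file-safe (``LF_HF`` for the LF/HF ratio);
    floats are written at full precision for lossless reload.
    """
    df = vectors if isinstance(vectors, pd.DataFrame) else vectors_to_frame(vectors)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise OxiscreenError("feature table lacks a subject_id column")
    return df


def frame_to_vectors(df: pd.DataFrame) -> list[SubjectFeatureVector]:
    """Inverse of ``vectors_to_frame``."""
    meta = {"subject_id", "label", "ahi", "n_valid_windows"}
    cols = [c for c in df.columns if c not in meta]
    out = []
    for _, row in df.iterrows():
        ahi = row.get("ahi", np.nan)
        out.append(SubjectFeatureVector(
            subject_id=str(row["subject_id"]),
            features={c: float(row[c]) for c in cols},
            n_valid_windows=int(row.get("n_valid_windows", 0)),
            label=str(row.get("label", UNKNOWN)),
            ahi=None if pd.isna(ahi) else float(ahi),
        ))
    return out
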