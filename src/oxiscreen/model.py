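"""Core data model: overnight oximetry recordings and sliding analysis windows.

An overnight recording carries two synchronized channels from a pulse
oximeter: blood oxygen saturation (SpO2, nominally 1 Hz at 0.1% resolution)
and the photoplethysmogram (PPG, nominally 62.5 Hz, arbitrary units).
Feature extraction operates on 2-minute windows advanced in 1-minute hops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

SDB = "SDB"
NONSDB = "NonSDB"
UNKNOWN = "unknown"

#: Recordings shorter than this are flagged (usable-signal exclusion rule).
MIN_RECOMMENDED_DURATION_S = 3 * 3600.0


class OxiscreenError(Exception):
    """Base class for all package errors."""


class ChannelMissingError(OxiscreenError):
    """A required channel is absent from an input file."""


class InconsistentSamplingError(OxiscreenError):
    """A channel's sampling rate is inconsistent or cannot be established."""


class RecordingTooShortError(OxiscreenError):
    """The recording is shorter than a single analysis window."""


class FeatureTableError(OxiscreenError):
    """Feature-table rows do not share a common feature set, or table is empty."""


def label_from_ahi(ahi: float, threshold: float = 5.0) -> str:
    """Binary SDB label from the reference apnea-hypopnea index.

    Children with AHI at or above ``threshold`` events/hour (default 5,
    the treatment-referral practice the labels follow) are labelled SDB.
    """
    return SDB if ahi >= threshold else NONSDB


@dataclass
class OximetryRecording:
    """Two-channel overnight pulse-oximetry recording plus subject metadata.

    SpO2 values are percentages; samples outside [0, 100] are permitted at
    construction (they are retained but flagged as artifacts downstream).
    Missing samples are NaN, never silently dropped.
    """

    subject_id: str
    spo2: np.ndarray
    ppg: np.ndarray
    spo2_fs: float = 1.0
    ppg_fs: float = 62.5
    spo2_resolution: float = 0.1
    ahi: float | None = None
    label: str = UNKNOWN
    ahi_threshold: float = 5.0

    def __post_init__(self) -> None:
        self.spo2 = np.asarray(self.spo2, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.spo2.ndim != 1 or self.ppg.ndim != 1:
            raise OxiscreenError("spo2 and ppg must be one-dimensional series")
        if self.spo2_fs <= 0 or self.ppg_fs <= 0:
            raise InconsistentSamplingError("sampling rates must be positive")
        d_spo2 = self.spo2.size / self.spo2_fs
        d_ppg = self.ppg.size / self.ppg_fs
        if abs(d_spo2 - d_ppg) > 1.0 / self.spo2_fs:
            raise InconsistentSamplingError(
                f"channel durations disagree: SpO2 {d_spo2:.2f} s vs PPG {d_ppg:.2f} s "
                f"(more than one SpO2 sample apart)"
            )
        if self.ahi is not None and self.label == UNKNOWN:
            self.label = label_from_ahi(self.ahi, self.ahi_threshold)

    @property
    def duration_s(self) -> float:
        """Recording duration in seconds (SpO2 clock)."""
        return self.spo2.size / self.spo2_fs

    @property
    def is_short(self) -> bool:
        """True when the recording is shorter than 3 h (flag, not rejection)."""
        return self.duration_s < MIN_RECOMMENDED_DURATION_S


@dataclass
class AnalysisWindow:
    """One 2-minute segment of both channels, aligned to the SpO2 clock.

    ``spo2_artifact_mask`` is True where a sample is an artifact (masked).
    ``ppg_quality_ok`` is set by the signal-quality gate; it defaults to
    True until the gate runs.
    """

    index: int
    start_s: float
    spo2_segment: np.ndarray
    ppg_segment: np.ndarray
    spo2_artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    ppg_quality_ok: bool = True

    def __post_init__(self) -> None:
        if self.spo2_artifact_mask is None:
            self.spo2_artifact_mask = ~np.isfinite(self.spo2_segment)
        if len(self.spo2_artifact_mask) != len(self.spo2_segment):
            raise OxiscreenError("artifact mask length differs from SpO2 segment")


def n_windows(duration_s: float, window_s: float, hop_s: float) -> int:
    """Number of complete sliding windows: floor((duration - window)/hop) + 1."""
    if duration_s < window_s:
        return 0
    return int(math.floor((duration_s - window_s) / hop_s + 1e-9)) + 1


def segment_windows(
    rec: OximetryRecording,
    window_s: float = 120.0,
    hop_s: float = 60.0,
    spo2_mask: np.ndarray | None = None,
    ppg: np.ndarray | None = None,
) -> list[AnalysisWindow]:
    """Tile a recording into overlapping analysis windows.

    The final partial window is discarded.  ``spo2_mask``/``ppg`` may supply
    a precomputed whole-night artifact mask and filtered PPG; otherwise the
    raw channels are sliced.

    Raises
    ------
    RecordingTooShortError
        If the recording is shorter than one window.
    """
    if hop_s > window_s:
        raise OxiscreenError("hop_s must not exceed window_s")
    count = n_windows(rec.duration_s, window_s, hop_s)
    if count == 0:
        raise RecordingTooShortError(
            f"recording of {rec.duration_s:.0f} s is shorter than one "
            f"{window_s:.0f} s window"
        )
    ppg_src = rec.ppg if ppg is None else np.asarray(ppg, dtype=float)
    windows: list[AnalysisWindow] = []
    for i in range(count):
        start_s = i * hop_s
        s0 = int(round(start_s * rec.spo2_fs))
        s1 = s0 + int(round(window_s * rec.spo2_fs))
        p0 = int(round(start_s * rec.ppg_fs))
        p1 = p0 + int(round(window_s * rec.ppg_fs))
        seg = rec.spo2[s0:s1]
        mask = None if spo2_mask is None else np.asarray(spo2_mask[s0:s1], bool)
        windows.append(
            AnalysisWindow(
                index=i,
                start_s=start_s,
                spo2_segment=seg,
                ppg_segment=ppg_src[p0:p1],
                spo2_artifact_mask=mask,
            )
        )
    return windows
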