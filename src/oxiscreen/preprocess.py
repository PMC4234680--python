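"""Signal cleaning: SpO2 artifact masking, PPG filtering, and quality gating.

SpO2 artifact rules: values below 50% or above 100%, and changes of more
than 4 percentage points relative to the previous *retained* sample, are
masked.  Comparing against the last retained sample (rather than the
previous raw sample) means an isolated spike masks only itself: the
recovery sample is kept whenever it is within 4 points of the pre-spike
level, preserving genuine desaturation recoveries.

PPG conditioning: median-filter baseline removal followed by a
Savitzky-Golay smoothing filter (polynomial order 3, frame 11 samples).
Windows are gated on a beat-template signal quality index (SQI): the mean
Pearson correlation between individual detected beats and the window's
ensemble-mean beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .config import DEFAULT_CONFIG, PipelineConfig

QUALITY_OK = "ok"
QUALITY_MOTION = "motion"
QUALITY_FLATLINE = "flatline"
QUALITY_INSUFFICIENT = "insufficient_valid_samples"


@dataclass
class QualityReport:
    """Per-window PPG quality decision."""

    window_index: int
    sqi: float
    reject: bool
    reason: str

    def __post_init__(self) -> None:
        assert self.reject == (self.reason != QUALITY_OK)


def clean_spo2(
    spo2: np.ndarray,
    resolution: float = 0.1,
    spo2_min: float = 50.0,
    spo2_max: float = 100.0,
    max_jump: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask SpO2 artifacts; return (series with NaN at masked samples, mask).

    A sample is masked when it is non-finite, outside [spo2_min, spo2_max],
    or differs from the last retained sample by more than ``max_jump``
    percentage points.  Masked samples are excluded from all downstream
    statistics; nothing is interpolated here.  The operation is idempotent.
    """
    x = np.asarray(spo2, dtype=float)
    mask = np.zeros(x.size, dtype=bool)
    cleaned = x.copy()
    last: float | None = None
    for i in range(x.size):
        v = x[i]
        if not np.isfinite(v) or v < spo2_min or v > spo2_max:
            mask[i] = True
            cleaned[i] = np.nan
            continue
        if last is not None and abs(v - last) > max_jump:
            mask[i] = True
            cleaned[i] = np.nan
            continue
        last = v
    return cleaned, mask


def filter_ppg(
    ppg: np.ndarray,
    fs: float = 62.5,
    sg_order: int = 3,
    sg_frame: int = 11,
    baseline_frame: int = 127,
) -> np.ndarray:
    """Baseline-removed, Savitzky-Golay-smoothed PPG; length preserved.

    Baseline removal is a two-stage running-median cascade: a
    ``baseline_frame``-sample (~2 s) median removes offset and slow
    drift, and a half-width median on the residual removes the remaining
    respiratory-band wander that the first stage is too wide to track.
    Median detrending is shift-free and positively homogeneous.  The
    residual is then smoothed with a Savitzky-Golay filter (order
    ``sg_order``, frame ``sg_frame``).  Segments shorter than the frame
    pass through unchanged (degenerate input).
    """
    x = np.asarray(ppg, dtype=float)
    if x.size < max(sg_frame, 3):
        return x.copy()

    def odd(n: int) -> int:
        n = min(n, x.size if x.size % 2 else x.size - 1)
        return n if n % 2 else n - 1

    y = x - median_filter(x, size=odd(baseline_frame), mode="nearest")
    y = y - median_filter(y, size=odd(baseline_frame // 2), mode="nearest")
    return savgol_filter(y, sg_frame, sg_order)


def _beat_matrix(x: np.ndarray, peaks: np.ndarray, half: int) -> np.ndarray:
    """Stack fixed-length beat segments centered on peak indices."""
    rows = []
    for p in peaks:
        if p - half < 0 or p + half >= x.size:
            continue
        rows.append(x[p - half : p + half + 1])
    return np.asarray(rows)


def assess_ppg_quality(
    window_ppg: np.ndarray,
    fs: float = 62.5,
    window_index: int = 0,
    cfg: PipelineConfig = DEFAULT_CONFIG,
    peak_times: np.ndarray | None = None,
) -> QualityReport:
    """Template-matching SQI for one filtered PPG window.

    The SQI is the mean Pearson correlation (negative values clipped to 0)
    between each detected beat and the ensemble-mean beat of the window.
    Rejection reasons: ``flatline`` (near-zero amplitude or no detectable
    pulses), ``insufficient_valid_samples`` (plausible pulse intervals
    cover less than ``min_valid_fraction`` of the window), ``motion``
    (SQI below ``sqi_threshold``).
    """
    from .prv import detect_pulse_peaks  # local import to avoid a cycle

    x = np.asarray(window_ppg, dtype=float)
    duration = x.size / fs

    def report(sqi: float, reason: str) -> QualityReport:
        return QualityReport(window_index, sqi, reason != QUALITY_OK, reason)

    if x.size == 0 or float(np.nanstd(x)) < 1e-12:
        return report(0.0, QUALITY_FLATLINE)
    if peak_times is None:
        peak_times = detect_pulse_peaks(x, fs, refractory_s=cfg.refractory_s)
    if peak_times.size < 3:
        return report(0.0, QUALITY_FLATLINE)
    intervals = np.diff(peak_times)
    plausible = (intervals >= cfg.ppi_min) & (intervals <= cfg.ppi_max)
    coverage = float(intervals[plausible].sum()) / duration
    if coverage < cfg.min_valid_fraction:
        return report(0.0, QUALITY_INSUFFICIENT)

    peaks = np.asarray(np.round(peak_times * fs), dtype=int)
    half = max(3, int(round(0.4 * float(np.median(intervals[plausible])) * fs)))
    beats = _beat_matrix(x, peaks, half)
    if beats.shape[0] < 3:
        return report(0.0, QUALITY_INSUFFICIENT)
    template = beats.mean(axis=0)
    bc = beats - beats.mean(axis=1, keepdims=True)
    tc = template - template.mean()
    denom = np.sqrt((bc**2).sum(axis=1) * (tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (bc @ tc) / denom
    corr = np.clip(np.nan_to_num(corr), 0.0, 1.0)
    sqi = float(corr.mean())
    if sqi < cfg.sqi_threshold:
        return report(sqi, QUALITY_MOTION)
    return report(sqi, QUALITY_OK)
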