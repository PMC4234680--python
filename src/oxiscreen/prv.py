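"""Pulse rate variability: beat detection, interval censoring, Berger
resampling, and time/frequency-domain features.

The pulse-to-pulse interval (PPI) series derived from the PPG stands in
for the ECG RR series.  Peaks are found with a zero-crossing detector on
the baseline-removed signal; intervals outside [0.33, 1.5] s are censored
as artifacts (the gap is kept, never re-linked).  For spectral analysis
the interval series is converted to a uniform 4 Hz series with Berger's
windowed-count method and modelled with a fixed-order AR(16) spectrum.
Band powers: VLF 0.01-0.04, LF 0.04-0.15, HF 0.15-0.4 Hz; normalized LF
and HF divide by the total power in 0.04-0.4 Hz, so they sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ar
from .config import DEFAULT_CONFIG, PipelineConfig


@dataclass
class PPISeries:
    """Pulse-to-pulse intervals of one window, with censoring bookkeeping."""

    peak_times: np.ndarray                 # seconds
    intervals: np.ndarray                  # all successive differences
    interval_valid: np.ndarray             # censoring mask (True = retained)
    rejected_count: int
    uniform_times: np.ndarray | None = None
    uniform_series: np.ndarray | None = None   # seconds, at resample_fs
    valid: bool = True
    invalid_reason: str = ""

    @property
    def retained(self) -> np.ndarray:
        return self.intervals[self.interval_valid]


@dataclass
class PRVWindowFeatures:
    """PRV feature set of one window (NaN where undefined)."""

    rr_mean: float = np.nan
    sdnn: float = np.nan
    rmssd: float = np.nan
    vlf: float = np.nan
    lf: float = np.nan
    hf: float = np.nan
    lf_norm: float = np.nan
    hf_norm: float = np.nan
    lf_hf: float = np.nan
    valid: bool = False


def detect_pulse_peaks(
    filtered_ppg: np.ndarray,
    fs: float = 62.5,
    refractory_s: float = 0.25,
    amplitude_gate: float = 0.3,
) -> np.ndarray:
    """Pulse peak times (s) via a zero-crossing detector.

    For each upward zero crossing followed by a downward crossing, the time
    of the maximum sample in between is emitted.  Candidate peaks closer
    than ``refractory_s`` are merged, keeping the larger one — this absorbs
    dicrotic-notch double crossings.  Candidates smaller than
    ``amplitude_gate`` times the 75th-percentile candidate amplitude are
    discarded: residual baseline wander can push small non-systolic bumps
    across zero, and those dwarf crossings are not pulses.
    """
    x = np.asarray(filtered_ppg, dtype=float)
    if x.size < 2:
        return np.zeros(0)
    pos = x > 0
    ups = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
    downs = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1
    if ups.size == 0 or downs.size == 0:
        return np.zeros(0)
    ends = np.searchsorted(downs, ups, side="right")
    pair_end = np.where(ends < downs.size, downs[np.minimum(ends, downs.size - 1)], x.size)
    candidates = [
        u + int(np.argmax(x[u:d])) for u, d in zip(ups, pair_end) if d > u
    ]
    if not candidates:
        return np.zeros(0)
    if amplitude_gate > 0 and len(candidates) >= 4:
        amps = x[np.asarray(candidates)]
        keep = amps >= amplitude_gate * np.percentile(amps, 75)
        candidates = [c for c, k in zip(candidates, keep) if k]
    merged: list[int] = []
    min_gap = refractory_s * fs
    for c in candidates:
        if merged and c - merged[-1] < min_gap:
            if x[c] > x[merged[-1]]:
                merged[-1] = c
        else:
            merged.append(c)
    return np.asarray(merged, dtype=float) / fs


def build_ppi_series(
    peak_times: np.ndarray, ppi_min: float = 0.33, ppi_max: float = 1.5
) -> PPISeries:
    """Successive peak differences with artifact censoring.

    Intervals outside [ppi_min, ppi_max] s are deleted; the series is not
    re-linked across the deletion (the gap remains and is handled by the
    resampler's gap policy).  Requires >= 3 peaks and >= 2 retained
    intervals.
    """
    t = np.asarray(peak_times, dtype=float)
    if t.size < 3:
        return PPISeries(t, np.zeros(0), np.zeros(0, bool), 0, valid=False,
                         invalid_reason="fewer than 3 peaks")
    intervals = np.diff(t)
    ok = (intervals >= ppi_min) & (intervals <= ppi_max)
    rejected = int(np.count_nonzero(~ok))
    series = PPISeries(t, intervals, ok, rejected)
    if np.count_nonzero(ok) < 2:
        series.valid = False
        series.invalid_reason = "fewer than 2 retained intervals"
    return series


def interval_count(ppi: PPISeries, times: np.ndarray) -> np.ndarray:
    """Fractional number of pulse intervals completed by each time.

    Piecewise-linear cumulative count over the peak grid (one unit per
    interval), linearly extended beyond the first/last peak with the edge
    interval's slope.  The Berger window count over [a, b] is F(b) - F(a).
    """
    t = ppi.peak_times
    counts = np.arange(t.size, dtype=float)
    out = np.interp(times, t, counts)
    before = times < t[0]
    after = times > t[-1]
    if before.any():
        out[before] = (times[before] - t[0]) / (t[1] - t[0])
    if after.any():
        out[after] = counts[-1] + (times[after] - t[-1]) / (t[-1] - t[-2])
    return out


def berger_resample(
    ppi: PPISeries,
    resample_fs: float = 4.0,
    span: tuple[float, float] | None = None,
    max_gap_s: float = 3.0,
    min_coverage: float = 0.5,
) -> PPISeries:
    """Uniform interval series at ``resample_fs`` by Berger's method.

    At each output tick a window two output samples wide counts the
    (fractional) number of pulse intervals it contains; the local rate is
    that count divided by the window width and the stored value is the
    instantaneous interval 1/rate.  Censored intervals act as gaps: a gap
    longer than ``max_gap_s``, or retained-interval coverage below
    ``min_coverage`` of the span, invalidates the window.
    """
    out = ppi
    if not ppi.valid:
        return out
    lo, hi = span if span is not None else (ppi.peak_times[0], ppi.peak_times[-1])
    duration = hi - lo
    gaps = ppi.intervals[~ppi.interval_valid]
    if gaps.size and float(gaps.max()) > max_gap_s:
        out.valid = False
        out.invalid_reason = f"censored gap of {gaps.max():.2f} s exceeds {max_gap_s} s"
        return out
    coverage = float(ppi.retained.sum()) / duration if duration > 0 else 0.0
    if coverage < min_coverage:
        out.valid = False
        out.invalid_reason = "retained intervals cover too little of the window"
        return out
    n_out = int(np.floor(duration * resample_fs)) + 1
    ticks = lo + np.arange(n_out) / resample_fs
    w = 2.0 / resample_fs
    n = interval_count(ppi, ticks + w / 2) - interval_count(ppi, ticks - w / 2)
    rate = n / w
    with np.errstate(divide="ignore"):
        out.uniform_series = 1.0 / rate
    out.uniform_times = ticks
    if not np.all(np.isfinite(out.uniform_series)):
        out.valid = False
        out.invalid_reason = "zero local rate during resampling"
    return out


def prv_time_features(ppi: PPISeries) -> tuple[float, float, float]:
    """(rr_mean, sdnn, rmssd) in seconds over retained intervals.

    RMSSD uses successive differences between *adjacent* retained
    intervals only — differences across censored gaps are excluded.
    """
    kept = ppi.retained
    if kept.size < 2:
        raise ValueError("need >= 2 retained intervals")
    rr_mean = float(kept.mean())
    sdnn = float(kept.std(ddof=1))
    ok = ppi.interval_valid
    adjacent = ok[:-1] & ok[1:]
    diffs = np.diff(ppi.intervals)[adjacent]
    rmssd = float(np.sqrt(np.mean(diffs**2))) if diffs.size else np.nan
    return rr_mean, sdnn, rmssd


def prv_spectral_features(
    uniform_series: np.ndarray,
    resample_fs: float = 4.0,
    order: int = 16,
    n_grid: int = 256,
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> PRVWindowFeatures:
    """Band powers and ratios from the AR(16) PSD of the uniform series."""
    out = PRVWindowFeatures()
    x = np.asarray(uniform_series, dtype=float)
    if x.size < 64:
        return out
    spec = ar.fit_ar_psd(x, T=1.0 / resample_fs, order=order, n_grid=n_grid)
    if spec is None or not spec.stable:
        return out
    out.vlf = ar.band_power(spec.freqs, spec.psd, *cfg.vlf_band)
    out.lf = ar.band_power(spec.freqs, spec.psd, *cfg.lf_band)
    out.hf = ar.band_power(spec.freqs, spec.psd, *cfg.hf_band)
    total = ar.band_power(spec.freqs, spec.psd, cfg.lf_band[0], cfg.hf_band[1])
    if total > 0:
        out.lf_norm = out.lf / total
        out.hf_norm = out.hf / total
    out.lf_hf = out.lf / out.hf if out.hf > 0 else np.nan
    out.valid = True
    return out


def prv_window_features(
    window_ppg: np.ndarray,
    fs: float = 62.5,
    window_s: float | None = None,
    cfg: PipelineConfig = DEFAULT_CONFIG,
    peak_times: np.ndarray | None = None,
) -> tuple[PRVWindowFeatures, PPISeries | None]:
    """Full PRV chain for one filtered, quality-approved PPG window."""
    out = PRVWindowFeatures()
    x = np.asarray(window_ppg, dtype=float)
    x = x - np.median(x)
    peaks = peak_times if peak_times is not None else detect_pulse_peaks(x, fs, cfg.refractory_s)
    if peaks.size < 3:
        return out, None
    ppi = build_ppi_series(peaks, cfg.ppi_min, cfg.ppi_max)
    if not ppi.valid:
        return out, ppi
    out.rr_mean, out.sdnn, out.rmssd = prv_time_features(ppi)
    ppi = berger_resample(ppi, cfg.resample_fs, max_gap_s=cfg.max_gap_s,
                          min_coverage=cfg.min_coverage)
    if ppi.valid and ppi.uniform_series is not None:
        spectral = prv_spectral_features(
            ppi.uniform_series, cfg.resample_fs, cfg.prv_ar_order, cfg.prv_n_grid, cfg
        )
        out.vlf, out.lf, out.hf = spectral.vlf, spectral.lf, spectral.hf
        out.lf_norm, out.hf_norm = spectral.lf_norm, spectral.hf_norm
        out.lf_hf = spectral.lf_hf
        out.valid = spectral.valid
    return out, ppi
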