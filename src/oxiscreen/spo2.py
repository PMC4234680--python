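"""Per-window SpO2 features: time-domain statistics, desaturation indices,
regularity measures, and the AR-spectral modulation-band description.

Recurrent obstructive apneas produce pseudo-periodic desaturation trains;
in a 2-minute window their footprint is (i) raised variability (standard
deviation, interquartile range, delta index), (ii) countable dips below a
running baseline, and (iii) a spectral peak in the 0.005-0.1 Hz
"modulation band" of the SpO2 power spectral density.  Regularity is
quantified with approximate entropy, sample entropy, and the central
tendency measure, computed on the retained samples at the oximeter's
native 0.1% resolution (regularity values are resolution-sensitive, so no
re-quantization is applied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import ar
from .config import DEFAULT_CONFIG, PipelineConfig


@dataclass
class SpO2WindowFeatures:
    """SpO2 feature set of one analysis window (NaN where undefined)."""

    mean: float = np.nan
    median: float = np.nan
    std: float = np.nan
    iqr: float = np.nan
    delta_index: float = np.nan
    n2pct: float = np.nan
    t_below: float = np.nan
    ctm: float = np.nan
    apen: float = np.nan
    sampen: float = np.nan
    P: float = np.nan
    R: float = np.nan
    SE: float = np.nan
    mod_freq: float = np.nan
    valid: bool = False


def spo2_basic_stats(segment: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, median, std, iqr) over unmasked (finite) samples.

    Sample standard deviation (ddof=1); IQR = Q3 - Q1 with
    linear-interpolation quantiles.  Requires >= 2 valid samples.
    """
    x = np.asarray(segment, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need >= 2 valid samples for basic statistics")
    q1, q3 = np.percentile(x, [25, 75])
    return float(x.mean()), float(np.median(x)), float(x.std(ddof=1)), float(q3 - q1)


def delta_index(segment: np.ndarray, block_s: float = 12.0, fs: float = 1.0) -> float:
    """Delta index: mean absolute difference between consecutive block means.

    The window is divided into ``block_s``-second blocks; blocks with at
    least one valid sample contribute their mean.  Requires >= 2 blocks.
    """
    x = np.asarray(segment, dtype=float)
    n_block = int(round(block_s * fs))
    means = []
    for start in range(0, x.size - n_block + 1, n_block):
        block = x[start : start + n_block]
        block = block[np.isfinite(block)]
        if block.size:
            means.append(block.mean())
    if len(means) < 2:
        return np.nan
    return float(np.mean(np.abs(np.diff(means))))


def running_baseline(
    values: np.ndarray, horizon_s: float = 60.0, fs: float = 1.0
) -> np.ndarray:
    """Running median of the preceding ``horizon_s`` of valid samples.

    Initialized with the overall median of the valid samples so that early
    samples have a sensible reference.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        return np.full(x.size, np.nan)
    vals = x[finite]
    init = float(np.median(vals))
    horizon = max(1, int(round(horizon_s * fs)))
    k = vals.size
    # median of the preceding (exclusive) window, on the valid-sample axis
    base_valid = np.full(k, init)
    for j in range(10, min(horizon, k)):
        base_valid[j] = np.median(vals[:j])
    if k > horizon:
        sw = np.lib.stride_tricks.sliding_window_view(vals, horizon)[:-1]
        base_valid[horizon:] = np.median(sw, axis=1)
    out = np.full(x.size, init)
    out[finite] = base_valid
    if (~finite).any():
        # invalid positions inherit the last valid baseline (unused downstream)
        idx = np.where(finite, np.arange(x.size), -1)
        np.maximum.accumulate(idx, out=idx)
        out = np.where(idx >= 0, out[np.maximum(idx, 0)], init)
    return out


def count_desaturations(
    segment: np.ndarray,
    depth: float = 2.0,
    min_event_s: float = 3.0,
    baseline_s: float = 60.0,
    fs: float = 1.0,
) -> int:
    """Count desaturation events dipping >= ``depth`` % below baseline.

    An event is a maximal run of valid samples at or below
    (baseline - depth) lasting at least ``min_event_s``; the baseline is a
    running median of the preceding ``baseline_s`` of valid signal.
    Invalid samples break runs.
    """
    x = np.asarray(segment, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("no valid samples")
    base = running_baseline(x, baseline_s, fs)
    below = finite & (x <= base - depth)
    min_len = max(1, int(round(min_event_s * fs)))
    count = 0
    run = 0
    for flag in below:
        if flag:
            run += 1
        else:
            if run >= min_len:
                count += 1
            run = 0
    if run >= min_len:
        count += 1
    return count


def time_below(segment: np.ndarray, sat_threshold: float = 92.0, fs: float = 1.0) -> float:
    """Cumulative seconds spent strictly below ``sat_threshold`` %."""
    x = np.asarray(segment, dtype=float)
    return float(np.count_nonzero(np.isfinite(x) & (x < sat_threshold)) / fs)


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """(n-m+1, m) matrix of length-m templates."""
    n = x.size - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def approximate_entropy(segment: np.ndarray, m: int = 1, r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) with self-matches included (nats).

    Phi_m(r) is the mean log fraction of templates within Chebyshev
    distance r; ApEn = Phi_m - Phi_{m+1}.  Default tolerance
    r = 0.25 * SD of the segment.  A constant segment returns 0.
    """
    x = np.asarray(segment, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < m + 2:
        return np.nan
    sd = x.std()
    if r is None:
        r = 0.25 * sd
    if sd < 1e-14 or r <= 0:
        return 0.0

    def phi(mm: int) -> float:
        t = _embed(x, mm)
        # Chebyshev distances, all template pairs (self-matches included)
        d = np.max(np.abs(t[:, None, :] - t[None, :, :]), axis=2)
        c = np.count_nonzero(d <= r, axis=1) / t.shape[0]
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(segment: np.ndarray, m: int = 1, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r) = -ln(A/B), self-matches excluded (nats).

    B counts ordered template pairs (i != j) matching at length m, A at
    length m+1; both use the first n-m templates so every m-template has an
    (m+1)-extension.  Returns NaN (undefined) when A or B is zero; a
    constant series gives A = B and hence 0.
    """
    x = np.asarray(segment, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < m + 2:
        return np.nan
    sd = x.std()
    if r is None:
        r = 0.25 * sd

    tm = _embed(x, m)[: n - m]
    tm1 = _embed(x, m + 1)
    dm = np.max(np.abs(tm[:, None, :] - tm[None, :, :]), axis=2)
    dm1 = np.max(np.abs(tm1[:, None, :] - tm1[None, :, :]), axis=2)
    B = np.count_nonzero(dm <= r) - tm.shape[0]
    A = np.count_nonzero(dm1 <= r) - tm1.shape[0]
    if A == 0 or B == 0:
        return np.nan
    return float(-math.log(A / B))


def central_tendency_measure(segment: np.ndarray, rho: float = 0.25) -> float:
    """Fraction of second-difference scatter points inside radius ``rho``.

    Points are (x[i+1]-x[i], x[i+2]-x[i+1]); the CTM is the proportion with
    Euclidean norm < rho.  High values indicate a quiet, regular trace.
    """
    x = np.asarray(segment, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need >= 3 valid samples for CTM")
    d = np.diff(x)
    radii = np.hypot(d[:-1], d[1:])
    return float(np.count_nonzero(radii < rho) / radii.size)


def interpolate_gaps(
    segment: np.ndarray, max_gap_s: float = 5.0, fs: float = 1.0
) -> np.ndarray | None:
    """Linearly interpolate masked (NaN) runs no longer than ``max_gap_s``.

    Returns None when any gap (including leading/trailing runs) exceeds the
    limit — the window is then invalid for spectral analysis, since long
    interpolations would fabricate low-frequency power.
    """
    x = np.asarray(segment, dtype=float)
    finite = np.isfinite(x)
    if finite.all():
        return x.copy()
    if not finite.any():
        return None
    max_run = int(round(max_gap_s * fs))
    # lengths of NaN runs
    run = 0
    for flag in finite:
        if not flag:
            run += 1
            if run > max_run:
                return None
        else:
            run = 0
    if run > max_run:
        return None
    idx = np.arange(x.size)
    out = x.copy()
    out[~finite] = np.interp(idx[~finite], idx[finite], x[finite])
    return out


def fit_ar_psd(
    segment: np.ndarray,
    T: float = 1.0,
    max_order: int = 30,
    n_grid: int = 256,
) -> ar.ARSpectrum | None:
    """AR PSD of a demeaned SpO2 segment, order selected by MDL (1..max)."""
    return ar.fit_ar_psd(segment, T=T, max_order=max_order, n_grid=n_grid)


def modulation_band_features(
    spec: ar.ARSpectrum,
    band_lo: float = 0.005,
    band_hi: float = 0.1,
    halfwidth: float = 0.01,
) -> tuple[float, float, float, float]:
    """(P, R, SE, mod_freq) from an SpO2 AR spectrum.

    mod_freq is the PSD argmax within [band_lo, band_hi]; P integrates the
    PSD over a 2*halfwidth interval centered there (clipped to the band);
    R = P / total power; SE is the Shannon entropy (bits) of the
    normalized PSD ordinates.
    """
    in_band = (spec.freqs >= band_lo) & (spec.freqs <= band_hi)
    if not in_band.any():
        raise ValueError("modulation band outside the PSD grid")
    band_freqs = spec.freqs[in_band]
    band_psd = spec.psd[in_band]
    mod_freq = float(band_freqs[np.argmax(band_psd)])
    lo = max(mod_freq - halfwidth, band_lo)
    hi = min(mod_freq + halfwidth, band_hi)
    P = ar.band_power(spec.freqs, spec.psd, lo, hi)
    total = ar.total_power(spec)
    R = P / total if total > 0 else np.nan
    SE = ar.spectral_entropy_bits(spec.psd)
    return P, R, SE, mod_freq


def spo2_window_features(
    segment: np.ndarray,
    artifact_mask: np.ndarray | None = None,
    cfg: PipelineConfig = DEFAULT_CONFIG,
    fs: float = 1.0,
) -> SpO2WindowFeatures:
    """All SpO2 features of one cleaned window.

    The window is invalid when more than ``cfg.max_missing_fraction`` of it
    is masked.  Time-domain and regularity features use the retained
    samples; the AR spectrum uses the segment with short gaps (at most
    ``cfg.max_interp_gap_s``) linearly interpolated onto the uniform grid.
    """
    x = np.asarray(segment, dtype=float).copy()
    if artifact_mask is not None:
        x[np.asarray(artifact_mask, bool)] = np.nan
    finite = np.isfinite(x)
    out = SpO2WindowFeatures()
    if finite.size == 0 or (1.0 - finite.mean()) > cfg.max_missing_fraction:
        return out
    if np.count_nonzero(finite) < 2:
        return out

    out.mean, out.median, out.std, out.iqr = spo2_basic_stats(x)
    out.delta_index = delta_index(x, cfg.delta_block_s, fs)
    out.n2pct = float(
        count_desaturations(x, cfg.desat_depth, cfg.desat_min_s, cfg.desat_baseline_s, fs)
    )
    out.t_below = time_below(x, cfg.sat_threshold, fs)
    valid_vals = x[finite]
    if valid_vals.size >= 3:
        out.ctm = central_tendency_measure(valid_vals, cfg.ctm_rho)
    if valid_vals.size >= 10 * max(cfg.apen_m, 1):
        r = cfg.apen_r_factor * float(valid_vals.std())
        out.apen = approximate_entropy(valid_vals, cfg.apen_m, r)
        out.sampen = sample_entropy(valid_vals, cfg.apen_m, r)

    interp = interpolate_gaps(x, cfg.max_interp_gap_s, fs)
    if interp is not None:
        spec = fit_ar_psd(interp, T=1.0 / fs, max_order=cfg.ar_max_order, n_grid=cfg.n_grid)
        if spec is not None:
            out.P, out.R, out.SE, out.mod_freq = modulation_band_features(
                spec, cfg.band_lo, cfg.band_hi, cfg.band_halfwidth
            )
    out.valid = True
    return out
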