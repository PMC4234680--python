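"""Synthetic overnight oximetry: SpO2 + PPG recordings with known ground truth.

The generator emulates the signal structure the screening chain relies
on, without claiming physiological waveform realism:

* SpO2 — a quantized (0.1%) baseline with slow AR(1) physiological noise
  and pseudo-periodic trains of trapezoidal desaturations.  The train
  period sets the SpO2 modulation frequency (1/period, in the
  0.005-0.1 Hz band for apnea-like periods of 10-200 s).
* PPG — a pulse train whose beat-to-beat intervals carry respiratory
  sinus arrhythmia (HF, ~0.25 Hz), a low-frequency oscillation (~0.1 Hz),
  beat-timing noise, and — in SDB-like recordings — sympathetic
  tachycardia/bradycardia swings time-locked to the planted desaturation
  events.  Beats are rendered as an asymmetric two-Gaussian pulse plus
  baseline wander; optional motion-artifact bursts replace stretches of
  the signal with high-amplitude band-limited noise to exercise the
  quality gate.
* Cohorts — per-subject log-normal jitter around SDB / NonSDB group
  parameterizations so the groups overlap realistically; the planted
  desaturation rate doubles as the reference AHI.

Everything is driven by a single seed: the same seed reproduces the same
recording or cohort exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .model import OximetryRecording, label_from_ahi


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one simulated overnight recording."""

    duration_s: float = 28800.0          # full night
    spo2_fs: float = 1.0
    ppg_fs: float = 62.5
    spo2_baseline: tuple[float, float] = (97.0, 0.25)   # mean %, slow-noise SD
    desat_rate: float = 0.0              # events/hour (reference-AHI proxy)
    desat_period_s: float = 33.0         # in-train inter-event interval
    desat_depth: tuple[float, float] = (4.0, 1.0)       # mean, SD (%)
    desat_duration_s: float = 28.0       # fall 10 s + plateau + recover 15 s
    events_per_train: int = 8
    mean_hr: float = 76.0                # bpm
    rsa_freq: float = 0.25               # Hz (respiratory / HF)
    rsa_depth: float = 0.05              # fractional interval modulation
    lf_freq: float = 0.1                 # Hz
    lf_depth: float = 0.02
    hr_noise: float = 0.015              # beat-to-beat fractional jitter
    event_tachybrady_depth: float = 0.0  # fractional swing at planted events
    artifact_fraction: float = 0.0       # fraction of time with motion bursts
    quantization: float = 0.1            # SpO2 resolution (%)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


#: Group parameterizations for cohort simulation.  Directions follow the
#: observed SDB physiology: frequent pseudo-periodic desaturations, higher
#: heart rate, a higher LF:HF interval-modulation ratio, and event-locked
#: sympathetic surges in the SDB group.
SDB_DEFAULTS = SimulationConfig(
    desat_rate=20.0, desat_period_s=33.0, desat_depth=(4.0, 1.0),
    mean_hr=81.0, rsa_depth=0.050, lf_depth=0.037,
    event_tachybrady_depth=0.06, artifact_fraction=0.02,
)
NONSDB_DEFAULTS = SimulationConfig(
    desat_rate=1.4, desat_period_s=50.0, desat_depth=(3.0, 0.8),
    mean_hr=76.0, rsa_depth=0.055, lf_depth=0.030,
    event_tachybrady_depth=0.0, artifact_fraction=0.02,
)


def _desat_event_times(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-periodic event trains: clustered onsets with jittered period."""
    n_events = int(round(cfg.desat_rate * cfg.duration_s / 3600.0))
    if n_events <= 0:
        return np.zeros(0)
    per_train = max(1, cfg.events_per_train)
    n_trains = -(-n_events // per_train)
    # one slot per train, so trains do not overlap each other
    slot = cfg.duration_s / n_trains
    times: list[float] = []
    remaining = n_events
    for i in range(n_trains):
        k = min(per_train, remaining)
        remaining -= k
        train_len = k * cfg.desat_period_s
        lo = i * slot
        hi = max(lo + slot - train_len - cfg.desat_duration_s, lo + 1.0)
        start = rng.uniform(lo, hi)
        periods = cfg.desat_period_s * (1.0 + 0.1 * rng.standard_normal(k))
        onsets = start + np.cumsum(periods) - periods[0]
        times.extend(onsets.tolist())
    times = np.sort(np.asarray(times))
    return times[times < cfg.duration_s - cfg.desat_duration_s]


def _trapezoid_dip(duration_s: float, fall_s: float = 10.0, rise_s: float = 15.0) -> np.ndarray:
    """Unit-depth trapezoidal desaturation shape at 1 Hz."""
    plateau_s = max(duration_s - fall_s - rise_s, 1.0)
    fall = np.linspace(0.0, 1.0, int(fall_s) + 1)[1:]
    plateau = np.ones(int(plateau_s))
    rise = np.linspace(1.0, 0.0, int(rise_s) + 1)[1:]
    return np.concatenate([fall, plateau, rise])


def simulate_spo2(
    cfg: SimulationConfig, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the 1 Hz SpO2 channel; returns (series, event onset times).

    Baseline + AR(1) noise + planted trapezoidal desaturation dips,
    quantized to the configured resolution and clipped to stay above the
    50% artifact floor.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(cfg.duration_s * cfg.spo2_fs))
    mean, sd = cfg.spo2_baseline
    phi = 0.98
    innov = rng.standard_normal(n) * sd * np.sqrt(1 - phi**2)
    noise = signal.lfilter([1.0], [1.0, -phi], innov)
    x = mean + noise
    events = _desat_event_times(cfg, rng)
    if events.size:
        dip = _trapezoid_dip(cfg.desat_duration_s)
        for t0 in events:
            depth = max(0.5, rng.normal(*cfg.desat_depth))
            i0 = int(round(t0))
            i1 = min(i0 + dip.size, n)
            x[i0:i1] -= depth * dip[: i1 - i0]
    # decimal-correct quantization (84.3, not 843 * 0.1 = 84.30000000000001)
    inv = round(1.0 / cfg.quantization)
    x = np.round(x * inv) / inv
    return np.clip(x, 51.0, 100.0), events


def _event_modulation(
    cfg: SimulationConfig, events: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Event-locked interval modulation on a 1 s grid (tachy then brady)."""
    n = int(cfg.duration_s) + 2
    grid = np.zeros(n)
    if cfg.event_tachybrady_depth <= 0 or events.size == 0:
        return np.arange(n, dtype=float), grid
    tau = np.arange(-5.0, 41.0)
    kernel = cfg.event_tachybrady_depth * (
        -np.exp(-(((tau - 5.0) / 6.0) ** 2)) + np.exp(-(((tau - 22.0) / 8.0) ** 2))
    )
    for t0 in events:
        i0 = int(round(t0)) - 5
        for j, val in enumerate(kernel):
            i = i0 + j
            if 0 <= i < n:
                grid[i] += val
    return np.arange(n, dtype=float), grid


def simulate_beat_times(
    cfg: SimulationConfig, rng: np.random.Generator, events: np.ndarray
) -> np.ndarray:
    """Beat onset times whose interval series carries the configured LF/HF
    oscillations, jitter, and event-locked swings."""
    base = 60.0 / cfg.mean_hr
    phase_lf = rng.uniform(0, 2 * np.pi)
    phase_hf = rng.uniform(0, 2 * np.pi)
    grid_t, grid_mod = _event_modulation(cfg, events)
    beats = []
    t = float(rng.uniform(0, base))
    while t < cfg.duration_s:
        mod = (
            1.0
            + cfg.rsa_depth * np.sin(2 * np.pi * cfg.rsa_freq * t + phase_hf)
            + cfg.lf_depth * np.sin(2 * np.pi * cfg.lf_freq * t + phase_lf)
            + cfg.hr_noise * rng.standard_normal()
            + np.interp(t, grid_t, grid_mod)
        )
        beats.append(t)
        t += float(np.clip(base * mod, 0.35, 1.45))
    return np.asarray(beats)


def _pulse_kernel(fs: float) -> np.ndarray:
    """Asymmetric two-Gaussian pulse shape (systolic peak + dicrotic hump)."""
    tau = np.arange(0.0, 0.75, 1.0 / fs)
    return (
        np.exp(-(((tau - 0.18) / 0.055) ** 2) / 2.0)
        + 0.30 * np.exp(-(((tau - 0.34) / 0.09) ** 2) / 2.0)
    )


def simulate_ppg(
    cfg: SimulationConfig,
    seed: int | np.random.Generator = 0,
    events: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the 62.5 Hz PPG channel; returns (series, beat times)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if events is None:
        events = np.zeros(0)
    beats = simulate_beat_times(cfg, rng, events)
    n = int(round(cfg.duration_s * cfg.ppg_fs))
    impulses = np.zeros(n)
    idx = np.asarray(np.round(beats * cfg.ppg_fs), dtype=int)
    idx = idx[idx < n]
    amps = 1.0 + 0.05 * rng.standard_normal(idx.size)
    np.add.at(impulses, idx, amps)
    kernel = _pulse_kernel(cfg.ppg_fs)
    x = signal.fftconvolve(impulses, kernel)[:n]
    # peak offset: the kernel's systolic maximum lags the beat onset
    t = np.arange(n) / cfg.ppg_fs
    wander = 0.5 * np.sin(2 * np.pi * 0.23 * t + rng.uniform(0, 2 * np.pi))
    drift = signal.lfilter([1.0], [1.0, -0.999], 0.01 * rng.standard_normal(n))
    x = x + wander + drift + 0.02 * rng.standard_normal(n)
    if cfg.artifact_fraction > 0:
        x = _inject_motion_artifacts(x, cfg, rng)
    return x, beats


def _inject_motion_artifacts(
    x: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Replace bursts with high-amplitude band-limited noise (trips the SQI)."""
    n = x.size
    total = cfg.artifact_fraction * cfg.duration_s
    sos = signal.butter(2, [3.0, 12.0], "bandpass", fs=cfg.ppg_fs, output="sos")
    placed = 0.0
    out = x.copy()
    while placed < total:
        burst_s = float(rng.uniform(5.0, 15.0))
        start = int(rng.uniform(0, n - burst_s * cfg.ppg_fs))
        m = int(burst_s * cfg.ppg_fs)
        noise = signal.sosfilt(sos, rng.standard_normal(m))
        out[start : start + m] = 4.0 * noise
        placed += burst_s
    return out


def simulate_recording(
    cfg: SimulationConfig,
    seed: int | np.random.Generator = 0,
    subject_id: str = "SIM",
    ahi: float | None = None,
) -> tuple[OximetryRecording, dict]:
    """One synthetic recording plus its ground truth (event/beat times)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spo2, events = simulate_spo2(cfg, rng)
    ppg, beats = simulate_ppg(cfg, rng, events)
    rec = OximetryRecording(
        subject_id=subject_id, spo2=spo2, ppg=ppg,
        spo2_fs=cfg.spo2_fs, ppg_fs=cfg.ppg_fs,
        spo2_resolution=cfg.quantization,
        ahi=cfg.desat_rate if ahi is None else ahi,
    )
    truth = {"event_times": events, "beat_times": beats, "config": cfg}
    return rec, truth


def _jitter_config(
    cfg: SimulationConfig, rng: np.random.Generator, sdb: bool, ahi_threshold: float = 5.0
) -> SimulationConfig:
    """Per-subject log-normal parameter jitter around the group config.

    The planted desaturation rate is kept on the subject's side of the
    labelling threshold so group membership and label agree.
    """
    def ln(x: float, s: float) -> float:
        return float(x * rng.lognormal(0.0, s))

    rate = ln(cfg.desat_rate, 0.30) if cfg.desat_rate > 0 else 0.0
    rate = max(rate, ahi_threshold + 1.0) if sdb else min(rate, ahi_threshold - 1.0)
    depth_mean, depth_sd = cfg.desat_depth
    return cfg.replace(
        desat_rate=rate,
        desat_period_s=ln(cfg.desat_period_s, 0.15),
        desat_depth=(ln(depth_mean, 0.15), depth_sd),
        mean_hr=ln(cfg.mean_hr, 0.05),
        rsa_depth=ln(cfg.rsa_depth, 0.20),
        lf_depth=ln(cfg.lf_depth, 0.20),
        event_tachybrady_depth=(
            ln(cfg.event_tachybrady_depth, 0.20) if cfg.event_tachybrady_depth > 0 else 0.0
        ),
    )


def simulate_cohort(
    n_sdb: int = 56,
    n_nonsdb: int = 90,
    sdb_cfg: SimulationConfig = SDB_DEFAULTS,
    nonsdb_cfg: SimulationConfig = NONSDB_DEFAULTS,
    seed: int = 0,
    duration_s: float | None = None,
    ahi_threshold: float = 5.0,
) -> tuple[list[OximetryRecording], list[dict]]:
    """A labelled cohort of synthetic recordings (default 56 SDB / 90 NonSDB).

    Per-subject parameters are jittered log-normally around the group
    configuration; the planted desaturation rate serves as the reference
    AHI, so labels follow from the usual AHI >= 5 rule.  ``duration_s``
    overrides both groups' recording length (a problem-size knob, not an
    effect-size one).
    """
    rng = np.random.default_rng(seed)
    recordings: list[OximetryRecording] = []
    truths: list[dict] = []
    specs = [(sdb_cfg, True)] * n_sdb + [(nonsdb_cfg, False)] * n_nonsdb
    for i, (group_cfg, is_sdb) in enumerate(specs):
        cfg = group_cfg if duration_s is None else group_cfg.replace(duration_s=duration_s)
        cfg = _jitter_config(cfg, rng, is_sdb, ahi_threshold)
        rec, truth = simulate_recording(
            cfg, rng, subject_id=f"S{i:03d}", ahi=cfg.desat_rate
        )
        assert rec.label == label_from_ahi(cfg.desat_rate, ahi_threshold)
        recordings.append(rec)
        truths.append(truth)
    return recordings, truths
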