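"""End-to-end feature extraction: recording -> windowed features -> subject vector."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import preprocess, prv, spo2
from .aggregate import SubjectFeatureVector, aggregate_overnight, feature_names
from .config import DEFAULT_CONFIG, PipelineConfig
from .model import OximetryRecording, segment_windows


def extract_window_features(
    rec: OximetryRecording, cfg: PipelineConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-window feature table for one recording.

    The SpO2 channel is artifact-masked and the PPG filtered once over the
    whole night; each 2-minute window then yields the SpO2 feature set and,
    when the quality gate passes, the PRV feature set.  Invalid entries are
    NaN.  Extra bookkeeping columns (``sqi``, ``ppg_ok``) are included for
    reporting and are not features.
    """
    cleaned, mask = preprocess.clean_spo2(
        rec.spo2, rec.spo2_resolution, cfg.spo2_min, cfg.spo2_max, cfg.spo2_max_jump
    )
    filtered = preprocess.filter_ppg(
        rec.ppg, rec.ppg_fs, cfg.sg_order, cfg.sg_frame, cfg.baseline_frame
    )
    windows = segment_windows(rec, cfg.window_s, cfg.hop_s, spo2_mask=mask, ppg=filtered)
    t_name = cfg.t_below_name
    rows = []
    for w in windows:
        sp = spo2.spo2_window_features(
            w.spo2_segment, w.spo2_artifact_mask, cfg, fs=rec.spo2_fs
        )
        seg = w.ppg_segment - np.median(w.ppg_segment)
        peaks = prv.detect_pulse_peaks(seg, rec.ppg_fs, cfg.refractory_s)
        quality = preprocess.assess_ppg_quality(
            seg, rec.ppg_fs, w.index, cfg, peak_times=peaks
        )
        w.ppg_quality_ok = not quality.reject
        if quality.reject:
            pr = prv.PRVWindowFeatures()
        else:
            pr, _ = prv.prv_window_features(
                seg, rec.ppg_fs, cfg.window_s, cfg, peak_times=peaks
            )
        rows.append({
            "window": w.index,
            "start_s": w.start_s,
            "P": sp.P, "R": sp.R, "SE": sp.SE, "Delta": sp.delta_index,
            "iqr": sp.iqr, "std": sp.std, t_name: sp.t_below, "n2": sp.n2pct,
            "CTM": sp.ctm, "ApEn": sp.apen, "SampEn": sp.sampen,
            "mean": sp.mean, "median": sp.median, "mod_freq": sp.mod_freq,
            "LF": pr.lf_norm, "HF": pr.hf_norm, "LF_HF": pr.lf_hf,
            "RR": pr.rr_mean, "SDNN": pr.sdnn, "RMSSD": pr.rmssd,
            "sqi": quality.sqi, "ppg_ok": float(not quality.reject),
        })
    return pd.DataFrame(rows)


def extract_features(
    rec: OximetryRecording,
    cfg: PipelineConfig = DEFAULT_CONFIG,
    min_windows: int | None = None,
) -> SubjectFeatureVector:
    """Overnight M/Me/S/I feature vector for one recording."""
    table = extract_window_features(rec, cfg)
    cols = feature_names(cfg.t_below_name)
    return aggregate_overnight(
        table[cols],
        subject_id=rec.subject_id,
        label=rec.label,
        ahi=rec.ahi,
        min_windows=cfg.min_windows if min_windows is None else min_windows,
    )


def extract_cohort(
    recordings: list[OximetryRecording],
    cfg: PipelineConfig = DEFAULT_CONFIG,
    min_windows: int | None = None,
) -> pd.DataFrame:
    """Feature table over a cohort (one row per subject)."""
    from .aggregate import vectors_to_frame

    vectors = [extract_features(r, cfg, min_windows) for r in recordings]
    return vectors_to_frame(vectors)
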