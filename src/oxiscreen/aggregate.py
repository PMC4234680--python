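"""Overnight aggregation of windowed features and group-difference statistics.

Each windowed feature F is summarized over the night by its mean (M_F),
median (Me_F), standard deviation (S_F), and interquartile range (I_F),
giving the per-subject feature vector used for screening.  Group
differences between SDB and NonSDB subjects are assessed per feature:
Shapiro-Wilk normality in each group; Welch's unequal-variance t-test with
a 95% CI for normal features; otherwise a log transform (or Box-Cox when
the feature contains zeros) before the Welch test, plus a Mann-Whitney U
test on the original data.  Significance is flagged at a
Bonferroni-corrected alpha over the feature family being compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import NONSDB, SDB, FeatureTableError

AGG_PREFIXES = ("M", "Me", "S", "I")

#: Windowed feature names in canonical (reporting) order.  The
#: time-below feature is named after its threshold (t92 by default).
SPO2_FEATURES = ("P", "R", "SE", "Delta", "iqr", "std", "{t_below}", "n2", "CTM", "ApEn", "SampEn")
PRV_FEATURES = ("LF", "HF", "LF_HF", "RR", "SDNN", "RMSSD")

TRANSFORM_NONE = "none"
TRANSFORM_LOG = "log"
TRANSFORM_BOXCOX = "box-cox"


def feature_names(t_below_name: str = "t92") -> list[str]:
    """Canonical windowed feature names (17 of them)."""
    spo2 = [f.format(t_below=t_below_name) for f in SPO2_FEATURES]
    return spo2 + list(PRV_FEATURES)


def aggregate_names(t_below_name: str = "t92") -> list[str]:
    """All 68 per-subject aggregate names: M_F, Me_F, S_F, I_F per feature."""
    return [f"{p}_{f}" for f in feature_names(t_below_name) for p in AGG_PREFIXES]


@dataclass
class SubjectFeatureVector:
    """Per-subject overnight aggregates of every windowed feature."""

    subject_id: str
    features: dict[str, float]
    n_valid_windows: int
    label: str = "unknown"
    ahi: float | None = None
    usable: bool = True
    reason: str = ""


def aggregate_overnight(
    window_features: pd.DataFrame,
    subject_id: str = "",
    label: str = "unknown",
    ahi: float | None = None,
    min_windows: int = 60,
) -> SubjectFeatureVector:
    """M/Me/S/I aggregates over valid windows of each feature column.

    ``window_features`` has one row per window and one column per windowed
    feature, with NaN marking windows invalid for that feature.  All four
    statistics are permutation-invariant; S uses ddof=1 and I is Q3 - Q1.
    The vector is marked unusable when fewer than ``min_windows`` windows
    are valid for some feature.
    """
    feats: dict[str, float] = {}
    counts = []
    for col in window_features.columns:
        x = window_features[col].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        counts.append(x.size)
        if x.size >= 2:
            q1, q3 = np.percentile(x, [25, 75])
            feats[f"M_{col}"] = float(x.mean())
            feats[f"Me_{col}"] = float(np.median(x))
            feats[f"S_{col}"] = float(x.std(ddof=1))
            feats[f"I_{col}"] = float(q3 - q1)
        else:
            for p in AGG_PREFIXES:
                feats[f"{p}_{col}"] = np.nan
    n_valid = int(min(counts)) if counts else 0
    vec = SubjectFeatureVector(subject_id, feats, n_valid, label=label, ahi=ahi)
    if n_valid < min_windows:
        vec.usable = False
        vec.reason = f"only {n_valid} valid windows (< {min_windows})"
    return vec


def vectors_to_frame(vectors: list[SubjectFeatureVector]) -> pd.DataFrame:
    """Feature table: one row per subject, shared feature columns.

    Raises FeatureTableError on an empty list or heterogeneous feature
    sets (the symmetric difference is reported).
    """
    if not vectors:
        raise FeatureTableError("no subject feature vectors to tabulate")
    ref = set(vectors[0].features)
    for v in vectors[1:]:
        diff = ref.symmetric_difference(v.features)
        if diff:
            raise FeatureTableError(
                f"feature sets differ between subjects: {sorted(diff)}"
            )
    cols = list(vectors[0].features)
    rows = []
    for v in vectors:
        row = {"subject_id": v.subject_id, "label": v.label,
               "ahi": np.nan if v.ahi is None else v.ahi,
               "n_valid_windows": v.n_valid_windows}
        row.update({c: v.features[c] for c in cols})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class FeatureComparison:
    """Group-difference result for one aggregate feature."""

    feature: str
    mean_sdb: float
    sd_sdb: float
    mean_nonsdb: float
    sd_nonsdb: float
    mean_diff: float
    normality_p: float            # min of the two groups' Shapiro-Wilk p
    transform_used: str
    t_p: float                    # Welch t on the analysis scale
    mw_p: float                   # Mann-Whitney on original data
    ci_low: float
    ci_high: float
    significant_after_correction: bool
    skipped: bool = False
    skip_reason: str = ""


def _welch_with_ci(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(p, ci_low, ci_high) for Welch's t-test on mean(a) - mean(b)."""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # exactly-equal degenerate case: no evidence of a difference
        equal = float(a.mean()) == float(b.mean())
        return (1.0 if equal else 0.0), 0.0, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return float(res.pvalue), float(ci.low), float(ci.high)


def compare_groups(
    table: pd.DataFrame,
    features: list[str] | None = None,
    alpha: float = 0.05,
    label_col: str = "label",
) -> pd.DataFrame:
    """Per-feature SDB vs NonSDB comparison following the screening protocol.

    Both groups need >= 3 subjects.  The Bonferroni family is the set of
    features entering the table; the corrected threshold alpha/m is applied
    to the primary (Welch, analysis-scale) p-value.
    """
    y = table[label_col].to_numpy()
    if not ((y == SDB).sum() >= 3 and (y == NONSDB).sum() >= 3):
        raise ValueError("need >= 3 subjects in each of SDB and NonSDB")
    if features is None:
        skip = {label_col, "subject_id", "ahi", "n_valid_windows"}
        features = [c for c in table.columns if c not in skip]
    m = len(features)
    rows = []
    with warnings.catch_warnings():
        # near-constant aggregates (e.g. an all-zero time-below-threshold
        # column in one group) trip scipy's precision-loss warning; the
        # affected tests still return usable conservative p-values
        warnings.filterwarnings("ignore", message=".*Precision loss.*")
        rows = _compare_all(table, features, y, alpha, m)
    return pd.DataFrame([r.__dict__ for r in rows])


def _compare_all(table, features, y, alpha, m) -> list["FeatureComparison"]:
    rows: list[FeatureComparison] = []
    for feat in features:
        x = table[feat].to_numpy(dtype=float)
        g1 = x[(y == SDB) & np.isfinite(x)]
        g0 = x[(y == NONSDB) & np.isfinite(x)]
        base = dict(feature=feat,
                    mean_sdb=float(g1.mean()) if g1.size else np.nan,
                    sd_sdb=float(g1.std(ddof=1)) if g1.size > 1 else np.nan,
                    mean_nonsdb=float(g0.mean()) if g0.size else np.nan,
                    sd_nonsdb=float(g0.std(ddof=1)) if g0.size > 1 else np.nan)
        if g1.size < 3 or g0.size < 3:
            rows.append(FeatureComparison(
                **base, mean_diff=np.nan, normality_p=np.nan,
                transform_used=TRANSFORM_NONE, t_p=np.nan, mw_p=np.nan,
                ci_low=np.nan, ci_high=np.nan,
                significant_after_correction=False,
                skipped=True, skip_reason="too few valid subjects"))
            continue
        mean_diff = float(g1.mean() - g0.mean())
        degenerate = g1.std(ddof=1) == 0 and g0.std(ddof=1) == 0
        if degenerate:
            p_t, lo, hi = _welch_with_ci(g1, g0)
            rows.append(FeatureComparison(
                **base, mean_diff=mean_diff, normality_p=np.nan,
                transform_used=TRANSFORM_NONE, t_p=p_t, mw_p=p_t,
                ci_low=lo, ci_high=hi,
                significant_after_correction=False))
            continue
        with warnings.catch_warnings():
            # near-constant groups make Shapiro-Wilk noisy; its p-value is
            # only used to pick the analysis scale
            warnings.simplefilter("ignore")
            sw1 = stats.shapiro(g1).pvalue if g1.std(ddof=1) > 0 else 0.0
            sw0 = stats.shapiro(g0).pvalue if g0.std(ddof=1) > 0 else 0.0
        normality_p = float(min(sw1, sw0))
        mw_p = float(stats.mannwhitneyu(g1, g0, alternative="two-sided").pvalue)
        if normality_p > alpha:
            transform = TRANSFORM_NONE
            p_t, lo, hi = _welch_with_ci(g1, g0)
        else:
            combined = np.concatenate([g1, g0])
            has_zero = np.any(combined <= 0)
            if has_zero:
                transform = TRANSFORM_BOXCOX
                positive = combined[combined > 0]
                shift = (positive.min() / 2.0) if positive.size else 1.0
                shift -= min(0.0, float(combined.min()))
                _, lam = stats.boxcox(combined + shift)
                t1 = stats.boxcox(g1 + shift, lmbda=lam)
                t0 = stats.boxcox(g0 + shift, lmbda=lam)
            else:
                transform = TRANSFORM_LOG
                t1, t0 = np.log(g1), np.log(g0)
            if t1.std(ddof=1) == 0 and t0.std(ddof=1) == 0:
                p_t, lo, hi = 1.0, 0.0, 0.0
            else:
                p_t, lo, hi = _welch_with_ci(t1, t0)
        rows.append(FeatureComparison(
            **base, mean_diff=mean_diff, normality_p=normality_p,
            transform_used=transform, t_p=p_t, mw_p=mw_p,
            ci_low=lo, ci_high=hi,
            significant_after_correction=bool(p_t < alpha / m)))
    return rows
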