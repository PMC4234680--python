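"""Linear-discriminant screening with AUC-driven forward feature selection.

The screener is a two-class pooled-covariance linear discriminant with
fixed class priors (0.4 for SDB, matching the cohort's ~39% prevalence).
Candidate features must be statistically significant in a training-fold
group comparison; a greedy forward search then grows the feature subset,
at each step adding the feature that maximizes the leave-one-out
cross-validated AUC of the discriminant.  An external stratified N-fold
cross-validation (N = 4) wraps the whole procedure — test subjects never
influence feature selection or fitting in their fold.  Features selected
in at least 3 of the 4 folds form the consensus set used for the final
model.

The leave-one-out scores are computed with exact rank-one downdates of
the class means and pooled scatter, so the O(n) refits per candidate cost
about as much as a single fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .aggregate import compare_groups
from .model import NONSDB, SDB, OxiscreenError


class EmptyFeaturePoolError(OxiscreenError):
    """No feature passed the significance gate on a training fold."""


@dataclass
class ScreeningModel:
    """Fitted linear discriminant over a fixed feature list."""

    selected_features: list[str]
    weights: np.ndarray           # per-feature coefficients (z-scored space)
    intercept: float
    scale_mean: np.ndarray        # training means for z-scoring
    scale_sd: np.ndarray
    priors: tuple[float, float] = (0.4, 0.6)   # (SDB, NonSDB)
    decision_threshold: float = 0.5
    ridged: bool = False

    def decision_scores(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Linear discriminant scores (log posterior odds of SDB)."""
        Z = self._design(X)
        return Z @ self.weights + self.intercept

    def posterior(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Posterior probability of SDB per subject."""
        return expit(self.decision_scores(X))

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """1 = SDB, 0 = NonSDB at the posterior decision threshold."""
        return (self.posterior(X) >= self.decision_threshold).astype(int)

    def _design(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.selected_features if f not in X.columns]
            if missing:
                raise OxiscreenError(f"feature(s) missing from input: {missing}")
            X = X[self.selected_features].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.selected_features):
            raise OxiscreenError(
                f"expected {len(self.selected_features)} features, got {X.shape[1]}"
            )
        return (X - self.scale_mean) / self.scale_sd


def _lda_weights(
    X: np.ndarray, y: np.ndarray, priors: tuple[float, float]
) -> tuple[np.ndarray, float, bool]:
    """Pooled-covariance LDA in closed form; ridge fallback when singular."""
    X1, X0 = X[y == 1], X[y == 0]
    n1, n0 = len(X1), len(X0)
    m1, m0 = X1.mean(axis=0), X0.mean(axis=0)
    S = (X1 - m1).T @ (X1 - m1) + (X0 - m0).T @ (X0 - m0)
    cov = S / (n1 + n0 - 2)
    ridged = False
    try:
        cond = np.linalg.cond(cov)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e10:
        ridged = True
        cov = cov + np.eye(cov.shape[0]) * (1e-6 * max(np.trace(cov) / cov.shape[0], 1e-12))
    w = np.linalg.solve(cov, m1 - m0)
    b = -0.5 * (m1 + m0) @ w + np.log(priors[0] / priors[1])
    return w, float(b), ridged


def train_lda(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    priors: tuple[float, float] = (0.4, 0.6),
) -> ScreeningModel:
    """Fit the screener on (features, binary labels).

    Features are z-scored with training means/SDs before the discriminant
    is solved (LDA is affine-invariant in exact arithmetic; scaling
    stabilizes the covariance inverse).  Requires >= 2 subjects per class.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns) if feature_names is None else feature_names
        X = X[feature_names].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise OxiscreenError("need >= 2 subjects per class to fit the discriminant")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    w, b, ridged = _lda_weights(Z, y, priors)
    return ScreeningModel(
        selected_features=list(feature_names), weights=w, intercept=b,
        scale_mean=mu, scale_sd=sd, priors=priors, ridged=ridged,
    )


def auc_score(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC by the rank statistic, ties handled mid-rank."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def loo_scores(
    X: np.ndarray, y: np.ndarray, priors: tuple[float, float] = (0.4, 0.6)
) -> np.ndarray | None:
    """Leave-one-subject-out discriminant scores, exact and vectorized.

    For each left-out subject the class mean and pooled scatter are
    downdated by its rank-one contribution and the discriminant is
    re-solved.  Returns None when some training subset would be degenerate
    (a class with < 2 remaining subjects or a zero-variance direction).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, k = X.shape
    idx1, idx0 = y == 1, y == 0
    n1, n0 = int(idx1.sum()), int(idx0.sum())
    if n1 < 2 or n0 < 2:
        return None
    m1 = X[idx1].mean(axis=0)
    m0 = X[idx0].mean(axis=0)
    S = (X[idx1] - m1).T @ (X[idx1] - m1) + (X[idx0] - m0).T @ (X[idx0] - m0)
    if np.any(np.diag(S) <= 1e-12 * n):
        return None

    m_own = np.where(idx1[:, None], m1[None, :], m0[None, :])
    n_own = np.where(idx1, n1, n0).astype(float)
    v = X - m_own                                # deviation from own class mean
    alpha = n_own / (n_own - 1.0)
    # Downdated pooled scatter per left-out subject: S - alpha v v^T
    S_loo = S[None, :, :] - alpha[:, None, None] * v[:, :, None] * v[:, None, :]
    dof = n - 1 - 2
    cov = S_loo / dof
    # Downdated class means
    m1_loo = np.where(idx1[:, None], (n1 * m1[None, :] - X) / (n1 - 1), m1[None, :])
    m0_loo = np.where(idx0[:, None], (n0 * m0[None, :] - X) / (n0 - 1), m0[None, :])
    diff = m1_loo - m0_loo
    eye = np.eye(k) * 1e-9 * (np.trace(S) / (k * dof) + 1e-12)
    try:
        w = np.linalg.solve(cov + eye, diff[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        return None
    log_ratio = np.log(priors[0] / priors[1])
    return np.einsum("ij,ij->i", X - 0.5 * (m1_loo + m0_loo), w) + log_ratio


def loo_auc(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    feature_subset: list[str] | None = None,
    priors: tuple[float, float] = (0.4, 0.6),
) -> float | None:
    """Leave-one-out cross-validated AUC of the discriminant on a subset."""
    if isinstance(X, pd.DataFrame):
        X = X[feature_subset].to_numpy(dtype=float) if feature_subset else X.to_numpy(dtype=float)
    elif feature_subset is not None:
        raise ValueError("feature_subset requires a DataFrame input")
    scores = loo_scores(np.asarray(X, dtype=float), np.asarray(y, dtype=int), priors)
    if scores is None:
        return None
    return auc_score(scores, y)


def _rank_biserial(x1: np.ndarray, x0: np.ndarray) -> float:
    """|rank-biserial| effect size of the Mann-Whitney statistic."""
    u = stats.mannwhitneyu(x1, x0, alternative="two-sided").statistic
    return abs(2.0 * u / (len(x1) * len(x0)) - 1.0)


def forward_select(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    pool: list[str],
    max_features: int = 15,
    priors: tuple[float, float] = (0.4, 0.6),
) -> tuple[list[str], list[float]]:
    """Greedy forward selection maximizing the internal LOO AUC.

    Ties (identical AUC gains) are broken by the larger Mann-Whitney
    effect size on the training fold, then lexicographically.  Returns the
    selection order and the internal AUC after each addition.
    """
    if not pool:
        raise EmptyFeaturePoolError(
            "no features passed the significance gate on this training fold"
        )
    y_train = np.asarray(y_train, dtype=int)
    effect = {
        f: _rank_biserial(
            X_train.loc[y_train == 1, f].to_numpy(),
            X_train.loc[y_train == 0, f].to_numpy(),
        )
        for f in pool
    }
    Xmat = X_train[pool].to_numpy(dtype=float)
    col = {f: i for i, f in enumerate(pool)}
    selected: list[str] = []
    auc_path: list[float] = []
    remaining = sorted(pool)
    while remaining and len(selected) < max_features:
        best: tuple[float, float, str] | None = None  # (auc, effect, name)
        for f in remaining:
            cols = [col[s] for s in selected] + [col[f]]
            a = loo_auc(Xmat[:, cols], y_train, priors=priors)
            if a is None:
                continue
            key = (a, effect[f], f)
            if best is None or (key[0] > best[0] + 1e-12) or (
                abs(key[0] - best[0]) <= 1e-12
                and (key[1] > best[1] + 1e-12
                     or (abs(key[1] - best[1]) <= 1e-12 and key[2] < best[2]))
            ):
                best = key
        if best is None:
            break
        selected.append(best[2])
        auc_path.append(best[0])
        remaining.remove(best[2])
    return selected, auc_path


def compute_metrics(
    scores: np.ndarray, y: np.ndarray, threshold: float = 0.5
) -> dict:
    """Screening metrics (percent) from per-subject scores and labels.

    Confusion counts at ``threshold``; Sn = TP/(TP+FN), Sp = TN/(TN+FP),
    PPV = TP/(TP+FP), NPV = TN/(TN+FN), Acc = (TP+TN)/n, plus the
    referred fraction (TP+FP)/n and the trapezoidal ROC AUC.  Ratios with
    a zero denominator are reported as NaN (undefined), never as 0.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if (y == 1).sum() == 0 and (y == 0).sum() == 0:
        raise ValueError("empty label set")
    pred = scores >= threshold
    tp = int(np.count_nonzero(pred & (y == 1)))
    fn = int(np.count_nonzero(~pred & (y == 1)))
    tn = int(np.count_nonzero(~pred & (y == 0)))
    fp = int(np.count_nonzero(pred & (y == 0)))
    n = tp + fn + tn + fp

    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den else np.nan

    # ROC: sweep thresholds over unique scores (descending)
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    # collapse ties: keep last point of each distinct score
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n1] if n1 else np.full(2, np.nan)
    fpr = np.r_[0.0, fps[distinct] / n0] if n0 else np.full(2, np.nan)
    auc = float(np.trapezoid(tpr, fpr)) * 100 if n1 and n0 else np.nan
    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "accuracy": ratio(tp + tn, n),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "referred_pct": ratio(tp + fp, n),
        "auc": auc,
        "roc": np.column_stack([fpr, tpr]),
    }


def metrics_from_counts(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Screening metrics from confusion counts, via ``compute_metrics``.

    Builds the score/label set that realizes the counts at threshold 0.5
    (positives scored 1, negatives scored 0) and evaluates it.
    """
    scores = np.concatenate([np.ones(tp + fp), np.zeros(fn + tn)])
    y = np.concatenate([np.ones(tp), np.zeros(fp), np.ones(fn), np.zeros(tn)])
    return compute_metrics(scores, y.astype(int))


@dataclass
class FoldResult:
    fold: int
    selected_features: list[str]
    internal_auc_path: list[float]
    best_size: int
    test_metrics: dict
    test_index: np.ndarray


@dataclass
class CVReport:
    """Nested cross-validation report: per-fold results and consensus set."""

    folds: list[FoldResult]
    feature_histogram: dict[str, int]
    consensus_set: list[str]
    final_model: ScreeningModel | None
    seed: int

    @property
    def mean_test_auc(self) -> float:
        return float(np.mean([f.test_metrics["auc"] for f in self.folds]))

    def mean_metric(self, name: str) -> float:
        return float(np.nanmean([f.test_metrics[name] for f in self.folds]))

    def summary(self) -> dict:
        return {
            "mean_test_auc": self.mean_test_auc,
            "mean_accuracy": self.mean_metric("accuracy"),
            "mean_sensitivity": self.mean_metric("sensitivity"),
            "mean_specificity": self.mean_metric("specificity"),
            "mean_ppv": self.mean_metric("ppv"),
            "mean_npv": self.mean_metric("npv"),
            "consensus_set": self.consensus_set,
            "feature_histogram": self.feature_histogram,
        }


def significance_pool(
    X: pd.DataFrame, y: np.ndarray, alpha: float = 0.05, fallback: int = 5
) -> list[str]:
    """Features passing the group-difference gate on a training fold.

    The gate is the raw (uncorrected) primary p-value < alpha.  When no
    feature passes — e.g. under a permuted-label null — the ``fallback``
    smallest-p features are returned so the surrounding cross-validation
    can still estimate its (null) performance.
    """
    table = X.copy()
    table["label"] = np.where(np.asarray(y, int) == 1, SDB, NONSDB)
    comp = compare_groups(table, features=list(X.columns), alpha=alpha)
    usable = comp[~comp["skipped"]]
    sig = usable.loc[usable["t_p"] < alpha, "feature"].tolist()
    if sig:
        return sig
    order = usable.sort_values("t_p")["feature"].tolist()
    return order[:fallback]


def nested_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    n_folds: int = 4,
    seed: int = 0,
    priors: tuple[float, float] = (0.4, 0.6),
    max_features: int = 15,
    alpha: float = 0.05,
    consensus_min: int = 3,
    refit_full: bool = True,
) -> CVReport:
    """External stratified N-fold CV around gating + forward selection + LDA.

    Per fold: the significance gate and forward selection see only the
    training subjects; the subset size with the best internal LOO AUC is
    evaluated once on the held-out fold.  The feature histogram counts, for
    each feature, the folds whose (up to ``max_features``-long) selection
    contained it; features reaching ``consensus_min`` form the consensus
    set, refit on all data when ``refit_full``.
    """
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    hist: dict[str, int] = {}
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        X_tr, y_tr = X.iloc[tr], y[tr]
        X_te, y_te = X.iloc[te], y[te]
        pool = significance_pool(X_tr, y_tr, alpha=alpha)
        selected, auc_path = forward_select(
            X_tr, y_tr, pool, max_features=max_features, priors=priors
        )
        best_size = int(np.argmax(auc_path)) + 1 if auc_path else 0
        subset = selected[:best_size]
        model = train_lda(X_tr, y_tr, feature_names=subset, priors=priors)
        metrics = compute_metrics(model.posterior(X_te), y_te, model.decision_threshold)
        folds.append(FoldResult(fold, selected, auc_path, best_size, metrics, te))
        for f in selected:
            hist[f] = hist.get(f, 0) + 1
    consensus = sorted([f for f, c in hist.items() if c >= consensus_min])
    final = None
    if refit_full and consensus:
        final = train_lda(X, y, feature_names=consensus, priors=priors)
    return CVReport(folds, hist, consensus, final, seed)
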