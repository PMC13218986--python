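"""Evaluation battery for binary risk models, implemented from first principles.

Discrimination (confusion metrics, ROC/AUC by the Mann-Whitney midrank
formulation, step-interpolated average precision), accuracy of the
probability forecast (Brier score), calibration (equal-frequency binning
with the Hosmer-Lemeshow chi-square), clinical utility (decision-curve net
benefit against the treat-all / treat-none strategies), and the DeLong
test for paired AUC comparison via structural components.

Score ties are handled with midranks throughout (AUC and DeLong
placements).  The classification threshold for confusion-based metrics is
0.5 unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EvalReport",
    "CalibrationCurve",
    "DCACurve",
    "DeLongResult",
    "confusion_counts",
    "auc",
    "roc_points",
    "pr_points",
    "average_precision",
    "brier",
    "calibration",
    "hosmer_lemeshow",
    "decision_curve",
    "delong",
    "evaluate_probs",
    "evaluate",
    "group_chi2",
]

DEFAULT_THRESHOLDS = np.round(np.arange(0.01, 1.00, 0.01), 2)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes coded 0/1")
    return y


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------


def confusion_counts(probs, labels, threshold: float = 0.5) -> dict[str, int]:
    y = _check_binary(labels)
    pred = np.asarray(probs) >= threshold
    return {
        "TP": int(np.sum(pred & (y == 1))),
        "FP": int(np.sum(pred & (y == 0))),
        "TN": int(np.sum(~pred & (y == 0))),
        "FN": int(np.sum(~pred & (y == 1))),
    }


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with midranks for ties."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = sps.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) at every distinct threshold, from (0,0) to (1,1)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tp / y.sum()]
    fpr = np.r_[0.0, fp / (len(y) - y.sum())]
    return fpr, tpr


def pr_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) at every distinct descending threshold."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    npred = distinct + 1.0
    recall = tp / y.sum()
    precision = tp / npred
    return recall, precision


def average_precision(scores, labels) -> float:
    """Step-interpolated AP: sum (R_i - R_{i-1}) * P_i over thresholds."""
    recall, precision = pr_points(scores, labels)
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def brier(probs, labels) -> float:
    y = _check_binary(labels)
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationCurve:
    edges: np.ndarray
    mean_predicted: np.ndarray
    observed_rate: np.ndarray
    bin_counts: np.ndarray
    hl_statistic: float
    hl_df: int
    hl_p: float
    merged_bins: bool = False


def calibration(probs, labels, n_bins: int = 10, fitted: bool = False) -> CalibrationCurve:
    """Equal-frequency (decile) calibration bins and the Hosmer-Lemeshow test.

    HL statistic: sum over bins of (O - E)^2 / (E (1 - E/n_b)).  Degrees of
    freedom follow the classical theory: g - 2 when the probabilities were
    fit on these same data (``fitted=True``), g when they come from a
    locked model evaluated on held-out data (the default here, and the
    choice under which the test holds its nominal level on well-calibrated
    external probabilities).  Bins collapsed by duplicate quantile edges
    are merged (flagged on the result).
    """
    y = _check_binary(labels)
    p = np.asarray(probs, dtype=float)
    if len(p) < n_bins:
        raise ValueError("need at least one sample per bin")
    quantile_edges = np.quantile(p, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(quantile_edges)
    merged = len(edges) < len(quantile_edges)
    if len(edges) < 2:  # constant forecast: one bin holding every sample
        edges = np.array([edges[0], edges[0]])
    # assign by right-closed quantile bins; lowest edge inclusive
    idx = np.clip(np.searchsorted(edges, p, side="left") - 1, 0, len(edges) - 2)
    g = len(edges) - 1
    obs = np.zeros(g)
    exp = np.zeros(g)
    cnt = np.zeros(g)
    mean_pred = np.zeros(g)
    for b in range(g):
        m = idx == b
        cnt[b] = m.sum()
        obs[b] = y[m].sum()
        exp[b] = p[m].sum()
        mean_pred[b] = p[m].mean() if m.any() else np.nan
    keep = cnt > 0
    obs, exp, cnt, mean_pred = obs[keep], exp[keep], cnt[keep], mean_pred[keep]
    denom = exp * (1.0 - exp / cnt)
    valid = denom > 1e-12
    stat = float(np.sum((obs[valid] - exp[valid]) ** 2 / denom[valid]))
    g = int(keep.sum())
    df = max(g - 2 if fitted else g, 1)
    p_value = float(sps.chi2.sf(stat, df))
    return CalibrationCurve(edges, mean_pred, obs / cnt, cnt.astype(int), stat, df, p_value, merged)


def hosmer_lemeshow(
    probs, labels, n_bins: int = 10, fitted: bool = False
) -> tuple[float, int, float]:
    c = calibration(probs, labels, n_bins, fitted)
    return c.hl_statistic, c.hl_df, c.hl_p


# ---------------------------------------------------------------------------
# Decision curve analysis
# ---------------------------------------------------------------------------


@dataclass
class DCACurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


def decision_curve(probs, labels, thresholds=DEFAULT_THRESHOLDS) -> DCACurve:
    """Net benefit NB(p_t) = TP/N - FP/N * p_t/(1-p_t) across thresholds.

    Treat-all substitutes TP = all positives, FP = all negatives;
    treat-none is identically zero.  Thresholds at or above 1 are excluded.
    """
    y = _check_binary(labels)
    p = np.asarray(probs, dtype=float)
    t = np.asarray(thresholds, dtype=float)
    t = t[(t > 0) & (t < 1)]
    n = len(y)
    prevalence = y.mean()
    odds = t / (1.0 - t)
    tp = np.array([(p >= pt)[y == 1].sum() for pt in t], dtype=float)
    fp = np.array([(p >= pt)[y == 0].sum() for pt in t], dtype=float)
    nb = tp / n - fp / n * odds
    treat_all = prevalence - (1.0 - prevalence) * odds
    return DCACurve(t, nb, treat_all, np.zeros_like(t))


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    z: float
    p: float
    degenerate: bool = False


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-positive / per-negative structural components."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    tz = sps.rankdata(np.r_[pos, neg])
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    v_pos = (tz[:m] - tx) / n  # P(score_pos > score_neg) placement per positive
    v_neg = 1.0 - (tz[m:] - ty) / m
    auc_val = float(v_pos.mean())
    return auc_val, v_pos, v_neg


def delong(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong test for the difference of two correlated AUCs.

    Structural components (midrank placements) give per-model placement
    vectors over positives and negatives; their empirical covariances
    estimate var(AUC_A - AUC_B), and z = diff / sqrt(var) is referred to
    the standard normal (two-sided).
    """
    y = _check_binary(labels)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if len(sa) != len(y) or len(sb) != len(y):
        raise ValueError("score vectors and labels must align")
    auc_a, va_pos, va_neg = _placements(sa, y)
    auc_b, vb_pos, vb_neg = _placements(sb, y)
    m, n = len(va_pos), len(va_neg)
    s_pos = np.cov(np.vstack([va_pos, vb_pos]), ddof=1) if m > 1 else np.zeros((2, 2))
    s_neg = np.cov(np.vstack([va_neg, vb_neg]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s_pos / m + s_neg / n
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    diff = auc_a - auc_b
    if var <= 1e-16:
        degenerate = True
        z = 0.0
        p = 1.0
    else:
        degenerate = False
        z = diff / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, float(diff), max(var, 0.0), float(z), p, degenerate)


# ---------------------------------------------------------------------------
# Assembled report
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    ap: float
    brier: float
    confusion: dict[str, int]
    roc: tuple[np.ndarray, np.ndarray]
    pr: tuple[np.ndarray, np.ndarray]
    calibration: CalibrationCurve
    dca: DCACurve

    def metrics(self) -> dict[str, float]:
        return {
            "AUC": self.auc,
            "AP": self.ap,
            "Accuracy": self.accuracy,
            "Precision": self.precision,
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "F1": self.f1,
            "Brier": self.brier,
        }


def evaluate_probs(probs, labels, threshold: float = 0.5, n_bins: int = 10) -> EvalReport:
    y = _check_binary(labels)
    p = np.asarray(probs, dtype=float)
    cm = confusion_counts(p, y, threshold)
    tp, fp, tn, fn = cm["TP"], cm["FP"], cm["TN"], cm["FN"]
    n = tp + fp + tn + fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (
        2.0 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    return EvalReport(
        accuracy=(tp + tn) / n,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        auc=auc(p, y),
        ap=average_precision(p, y),
        brier=brier(p, y),
        confusion=cm,
        roc=roc_points(p, y),
        pr=pr_points(p, y),
        calibration=calibration(p, y, n_bins),
        dca=decision_curve(p, y),
    )


def evaluate(model, table: pd.DataFrame, label_col: str = "label", threshold: float = 0.5) -> EvalReport:
    """Full report from one probability pass of a fitted model."""
    from .model_lab import predict_proba  # late import avoids a cycle

    probs = predict_proba(model, table.drop(columns=[label_col]))
    return evaluate_probs(probs, table[label_col].to_numpy(), threshold)


def group_chi2(table_2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square (optional Yates continuity correction) for counts."""
    stat, p, _, _ = sps.chi2_contingency(np.asarray(table_2x2), correction=yates)
    return float(stat), float(p)
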