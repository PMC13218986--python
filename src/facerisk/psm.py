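"""Propensity-score matching on age and sex for baseline-balanced cohorts.

A logistic model of class on standardized age plus binary sex yields
propensity scores; greedy 1:1 nearest-neighbor matching without
replacement runs on the logit of the score with a caliper of 0.2 logit
SDs, the minority class driving the matching order (descending score).
Covariate balance is reported as standardized mean differences (SMD)
before and after matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = ["MatchResult", "propensity_scores", "nn_match", "standardized_mean_differences", "match_cohort"]


@dataclass
class MatchResult:
    pairs: np.ndarray  # (k, 2) row indices: [:, 0] class 1, [:, 1] class 0
    scores: np.ndarray
    caliper: float
    smd_pre: dict[str, float]
    smd_post: dict[str, float]

    @property
    def matched_indices(self) -> np.ndarray:
        return np.sort(self.pairs.ravel())

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _smd(x: np.ndarray, y01: np.ndarray) -> float:
    x1, x0 = x[y01 == 1], x[y01 == 0]
    v = (x1.var(ddof=1) + x0.var(ddof=1)) / 2.0
    if v == 0:
        return 0.0
    return float((x1.mean() - x0.mean()) / np.sqrt(v))


def standardized_mean_differences(
    table: pd.DataFrame, covariates, labels: np.ndarray
) -> dict[str, float]:
    y = np.asarray(labels).astype(int)
    return {c: _smd(table[c].to_numpy(dtype=float), y) for c in covariates}


def propensity_scores(
    table: pd.DataFrame, covariates=("age", "sex"), label_col: str = "label"
) -> np.ndarray:
    """P(class 1 | covariates) from an (effectively unpenalized) logistic fit."""
    X = table[list(covariates)].to_numpy(dtype=float)
    y = table[label_col].to_numpy().astype(int)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        warnings.warn("constant covariate(s); scores still defined", stacklevel=2)
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    lr = LogisticRegression(C=1e6, max_iter=2000)
    lr.fit(Z, y)
    return lr.predict_proba(Z)[:, 1]


def nn_match(scores: np.ndarray, labels: np.ndarray, caliper_sd: float = 0.2) -> "MatchResult":
    """Greedy caliper matching on logit propensity; equal matched group sizes."""
    y = np.asarray(labels).astype(int)
    s = np.clip(np.asarray(scores, dtype=float), 1e-12, 1 - 1e-12)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    logit = np.log(s / (1 - s))
    caliper = caliper_sd * float(logit.std(ddof=1))
    minority = 1 if (y == 1).sum() <= (y == 0).sum() else 0
    treated = np.flatnonzero(y == minority)
    controls = np.flatnonzero(y == 1 - minority)
    order = treated[np.argsort(-s[treated], kind="mergesort")]
    available = dict.fromkeys(controls.tolist())
    pairs = []
    for t in order:
        avail = np.fromiter(available.keys(), dtype=int)
        if len(avail) == 0:
            break
        d = np.abs(logit[avail] - logit[t])
        j = int(np.argmin(d))
        if d[j] <= caliper:
            c = int(avail[j])
            pairs.append((t, c) if minority == 1 else (c, t))
            del available[c]
    pairs_arr = (
        np.asarray(pairs, dtype=int) if pairs else np.empty((0, 2), dtype=int)
    )
    return MatchResult(pairs_arr, s, caliper, {}, {})


def match_cohort(
    table: pd.DataFrame,
    covariates=("age", "sex"),
    label_col: str = "label",
    caliper_sd: float = 0.2,
) -> tuple[pd.DataFrame, MatchResult]:
    """Full protocol: propensity fit, caliper matching, SMD balance table."""
    scores = propensity_scores(table, covariates, label_col)
    y = table[label_col].to_numpy().astype(int)
    result = nn_match(scores, y, caliper_sd)
    result.smd_pre = standardized_mean_differences(table, covariates, y)
    if result.n_pairs:
        matched = table.iloc[result.pairs.ravel()]
        result.smd_post = standardized_mean_differences(
            matched, covariates, matched[label_col].to_numpy()
        )
    else:
        result.smd_post = {c: np.nan for c in covariates}
    matched_table = (
        table.iloc[np.sort(result.pairs.ravel())].copy() if result.n_pairs else table.iloc[[]].copy()
    )
    return matched_table, result
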