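"""Stratified splitting, 10-fold CV with curve aggregation, and grid search
for the four classifier families (XGBoost, LightGBM, SVM, GBDT).

The split reproduces the development-cohort arithmetic: per-class test
allocation is round-half-up of class_n * (1 - train_fraction), adjusted so
the total equals ceil(N * (1 - train_fraction)); a 2299-row cohort with
1275/1024 class sizes therefore yields 1839 train / 460 test rows.

Seed policy: one run seed derives the split seed directly and per-fold
model seeds as ``seed * 100 + fold``, so a rerun with the same seed is
bit-reproducible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import eval_metrics as em

__all__ = [
    "FAMILIES",
    "DEFAULT_GRIDS",
    "ModelSpec",
    "FittedModel",
    "CVResult",
    "GridSearchResult",
    "stratified_split",
    "make_estimator",
    "cross_validate",
    "grid_search",
    "train_final",
    "predict_proba",
    "save_bundle",
    "load_bundle",
]

FAMILIES = ("xgb", "lgbm", "svm", "gbdt")

#: Small default grids (the optimal settings of the original study are not
#: published); grids are configuration, not code, and can be overridden.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "xgb": {"n_estimators": [100, 300], "max_depth": [3, 5], "learning_rate": [0.05, 0.1]},
    "lgbm": {"n_estimators": [100, 300], "num_leaves": [15, 31], "learning_rate": [0.05, 0.1]},
    "svm": {"C": [0.5, 1.0, 2.0], "gamma": ["scale", 0.05]},
    "gbdt": {"n_estimators": [100, 200], "max_depth": [2, 3], "learning_rate": [0.05, 0.1]},
}


@dataclass
class ModelSpec:
    family: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family '{self.family}'; expected one of {FAMILIES}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}


@dataclass
class FittedModel:
    """A trained classifier bound to its training feature schema."""

    estimator: object
    features: list[str]
    family: str
    params: dict
    seed: int = 0


@dataclass
class CVResult:
    fold_metrics: pd.DataFrame
    means: dict[str, float]
    sds: dict[str, float]
    curves: dict[str, dict[str, np.ndarray]]

    @property
    def mean_auc(self) -> float:
        return self.means["AUC"]


@dataclass
class GridSearchResult:
    best_params: dict
    best_auc: float
    results: list[tuple[dict, float]]
    model: FittedModel


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def stratified_split(
    table: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split with deterministic per-class allocation."""
    y = table[label_col].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    test_frac = 1.0 - train_fraction
    total_test = int(np.ceil(len(y) * test_frac))
    per_class = {
        c: int(np.floor(n * test_frac + 0.5)) for c, n in zip(classes, counts)
    }
    # adjust (largest classes first) so the totals match exactly
    delta = total_test - sum(per_class.values())
    order = [c for _, c in sorted(zip(-counts, classes))]
    i = 0
    while delta != 0:
        c = order[i % len(order)]
        per_class[c] += 1 if delta > 0 else -1
        delta += -1 if delta > 0 else 1
        i += 1
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        test_idx.append(rng.permutation(idx)[: per_class[c]])
    test_mask = np.zeros(len(y), dtype=bool)
    test_mask[np.concatenate(test_idx)] = True
    return table.loc[~test_mask].copy(), table.loc[test_mask].copy()


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def make_estimator(family: str, params: dict | None = None, seed: int = 0):
    params = dict(params or {})
    if family == "xgb":
        return XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss",
            tree_method="hist", **params,
        )
    if family == "lgbm":
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **params)
    if family == "svm":
        # sigmoid (Platt) calibration on inner CV, so the family emits
        # calibrated probabilities rather than margins
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    CalibratedClassifierCV(
                        SVC(kernel="rbf", random_state=seed, **params),
                        method="sigmoid",
                        cv=5,
                        ensemble=False,
                    ),
                ),
            ]
        )
    if family == "gbdt":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown family '{family}'")


def _raw_predict(estimator, X) -> np.ndarray:
    return np.clip(estimator.predict_proba(X)[:, 1], 0.0, 1.0)


def predict_proba(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Probabilities for new rows, after strict schema validation."""
    missing = [c for c in model.features if c not in table.columns]
    extra = [c for c in table.columns if c not in model.features and c != "label"]
    if missing or extra:
        raise ValueError(f"feature schema mismatch: missing={missing} extra={extra}")
    X = table[model.features].astype(float)
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError("non-finite feature values")
    return _raw_predict(model.estimator, X)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

_ROC_GRID = np.linspace(0.0, 1.0, 101)
_RECALL_GRID = np.linspace(0.0, 1.0, 101)
_CAL_GRID = np.linspace(0.05, 0.95, 10)

METRIC_NAMES = ("AUC", "AP", "Accuracy", "Precision", "Sensitivity", "Specificity", "F1")


def _fold_curves(probs: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    fpr, tpr = em.roc_points(probs, y)
    roc = np.interp(_ROC_GRID, fpr, tpr)
    recall, precision = em.pr_points(probs, y)
    order = np.argsort(recall)
    pr = np.interp(_RECALL_GRID, recall[order], precision[order])
    # equal-width bins for the plotted calibration curve
    cal = np.full(len(_CAL_GRID), np.nan)
    bins = np.clip((probs * 10).astype(int), 0, 9)
    for b in range(10):
        m = bins == b
        if m.any():
            cal[b] = y[m].mean()
    dca = em.decision_curve(probs, y)
    return {"roc": roc, "pr": pr, "calibration": cal, "dca": dca.net_benefit}


def cross_validate(
    spec: ModelSpec,
    train: pd.DataFrame,
    k: int = 10,
    seed: int | None = None,
    label_col: str = "label",
    params: dict | None = None,
) -> CVResult:
    """Stratified k-fold CV: per-fold metrics plus pointwise mean +/- SD curves."""
    seed = spec.seed if seed is None else seed
    y = train[label_col].to_numpy().astype(int)
    feats = [c for c in train.columns if c != label_col]
    X = train[feats].astype(float).reset_index(drop=True)
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError("non-finite feature values in the training table")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    curve_stacks: dict[str, list[np.ndarray]] = {"roc": [], "pr": [], "calibration": [], "dca": []}
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        est = make_estimator(spec.family, params, seed * 100 + fold)
        est.fit(X.iloc[tr], y[tr])
        probs = _raw_predict(est, X.iloc[va])
        rep = em.evaluate_probs(probs, y[va])
        rows.append({"fold": fold, **{m: rep.metrics()[m] for m in METRIC_NAMES}})
        for name, vals in _fold_curves(probs, y[va]).items():
            curve_stacks[name].append(vals)
    fold_metrics = pd.DataFrame(rows)
    means = {m: float(fold_metrics[m].mean()) for m in METRIC_NAMES}
    sds = {m: float(fold_metrics[m].std(ddof=1)) for m in METRIC_NAMES}
    xgrid = {"roc": _ROC_GRID, "pr": _RECALL_GRID, "calibration": _CAL_GRID,
             "dca": em.DEFAULT_THRESHOLDS}
    curves = {}
    import warnings as _warnings

    for name, stack in curve_stacks.items():
        arr = np.vstack(stack)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            curves[name] = {
                "x": xgrid[name],
                "mean": np.nanmean(arr, axis=0),
                "sd": np.nanstd(arr, axis=0, ddof=1),
            }
    return CVResult(fold_metrics, means, sds, curves)


def _grid_combinations(grid: dict[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def grid_search(
    spec: ModelSpec,
    train: pd.DataFrame,
    k: int = 10,
    seed: int | None = None,
    label_col: str = "label",
) -> GridSearchResult:
    """Exhaustive search maximizing mean CV AUC; ties keep the first setting.

    The winner is refit on the full training set.
    """
    seed = spec.seed if seed is None else seed
    results: list[tuple[dict, float]] = []
    best_auc = -np.inf
    best_params: dict = {}
    for params in _grid_combinations(spec.grid):
        cv = cross_validate(spec, train, k=k, seed=seed, label_col=label_col, params=params)
        results.append((params, cv.mean_auc))
        if cv.mean_auc > best_auc:
            best_auc = cv.mean_auc
            best_params = params
    model = train_final(spec, train, best_params, seed=seed, label_col=label_col)
    return GridSearchResult(best_params, float(best_auc), results, model)


def train_final(
    spec: ModelSpec,
    train: pd.DataFrame,
    params: dict | None = None,
    seed: int | None = None,
    label_col: str = "label",
) -> FittedModel:
    seed = spec.seed if seed is None else seed
    feats = [c for c in train.columns if c != label_col]
    est = make_estimator(spec.family, params, seed)
    est.fit(train[feats].astype(float), train[label_col].to_numpy().astype(int))
    return FittedModel(est, feats, spec.family, dict(params or {}), seed)


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------


def save_bundle(model: FittedModel, outdir, prep_stats=None) -> Path:
    """Fitted estimator + chosen hyperparameters + feature schema (+ prep stats)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.estimator, outdir / "estimator.joblib")
    (outdir / "params.json").write_text(json.dumps(model.params, indent=2, default=str))
    (outdir / "schema.json").write_text(
        json.dumps({"family": model.family, "features": model.features, "seed": model.seed}, indent=2)
    )
    if prep_stats is not None:
        prep_stats.save(outdir / "prep_stats.json")
    return outdir


def load_bundle(indir) -> FittedModel:
    indir = Path(indir)
    schema = json.loads((indir / "schema.json").read_text())
    params = json.loads((indir / "params.json").read_text())
    est = joblib.load(indir / "estimator.joblib")
    return FittedModel(est, schema["features"], schema["family"], params, schema.get("seed", 0))
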