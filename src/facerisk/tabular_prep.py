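"""Normality-dependent outlier replacement and missing-value imputation.

Per column of the feature table, fitted on training data only and replayed
unchanged on held-out data:

* If the column is compatible with normality (D'Agostino-Pearson K^2 at
  alpha = 0.05; Shapiro-Wilk below n = 50), outliers are cells with
  |Z| > 3 (sample SD, n-1) and are replaced with the column mean; missing
  cells are imputed with the mean.
* Otherwise bounds are Q1 - 1.5*IQR and Q3 + 1.5*IQR (linear-interpolation
  quartiles) and replacement/imputation uses the median.

Replacement statistics are computed from the original (pre-replacement)
non-missing values, which makes the transform idempotent and
order-independent.  Constant columns are flagged degenerate: no outlier is
possible and missing cells are imputed with the constant.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ColumnStats", "PrepStats", "fit_prep", "apply_prep"]

NORMALITY_ALPHA = 0.05
SHAPIRO_MAX_N = 50
Z_BOUND = 3.0
IQR_FACTOR = 1.5


@dataclass
class ColumnStats:
    name: str
    is_normal: bool
    degenerate: bool
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    lower: float
    upper: float
    n: int

    @property
    def replacement(self) -> float:
        return self.mean if self.is_normal else self.median


@dataclass
class PrepStats:
    """Fitted per-column statistics, JSON round-trippable for replay."""

    columns: dict[str, ColumnStats]

    def to_json(self) -> str:
        return json.dumps({k: asdict(v) for k, v in self.columns.items()}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PrepStats":
        return cls({k: ColumnStats(**v) for k, v in json.loads(text).items()})

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "PrepStats":
        return cls.from_json(Path(path).read_text())


def _is_normal(values: np.ndarray) -> bool:
    if np.ptp(values) == 0:
        return False
    try:
        if len(values) < SHAPIRO_MAX_N:
            p = sps.shapiro(values).pvalue
        else:
            p = sps.normaltest(values).pvalue
    except ValueError:
        return False
    return bool(p >= NORMALITY_ALPHA)


def fit_prep(table: pd.DataFrame, label_col: str = "label") -> PrepStats:
    """Fit per-column normality flags, bounds and replacement statistics."""
    columns: dict[str, ColumnStats] = {}
    for name in table.columns:
        if name == label_col or not pd.api.types.is_numeric_dtype(table[name]):
            continue
        values = table[name].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        if len(values) == 0:
            raise ValueError(f"column '{name}' is entirely missing")
        if len(values) < 3:
            raise ValueError(f"column '{name}' has fewer than 3 non-missing values")
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        q1, median, q3 = (float(v) for v in np.quantile(values, [0.25, 0.5, 0.75]))
        degenerate = sd == 0.0
        normal = False if degenerate else _is_normal(values)
        if degenerate:
            lower, upper = -np.inf, np.inf
        elif normal:
            lower, upper = mean - Z_BOUND * sd, mean + Z_BOUND * sd
        else:
            iqr = q3 - q1
            lower, upper = q1 - IQR_FACTOR * iqr, q3 + IQR_FACTOR * iqr
        columns[name] = ColumnStats(
            name, normal, degenerate, mean, sd, median, q1, q3, float(lower), float(upper), len(values)
        )
    return PrepStats(columns)


def apply_prep(table: pd.DataFrame, stats: PrepStats, label_col: str = "label") -> pd.DataFrame:
    """Replace out-of-bound cells and impute missing ones from fitted stats.

    Never recomputes anything from ``table``, so applying training-set
    statistics to a held-out table cannot leak held-out information.
    """
    out = table.copy()
    for name in table.columns:
        if name == label_col or not pd.api.types.is_numeric_dtype(table[name]):
            continue
        if name not in stats.columns:
            raise KeyError(f"column '{name}' present in table but absent from fitted stats")
        cs = stats.columns[name]
        col = out[name].to_numpy(dtype=float)
        bad = ~np.isfinite(col)
        bad |= (col < cs.lower) | (col > cs.upper)
        col[bad] = cs.replacement
        out[name] = col
    return out
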