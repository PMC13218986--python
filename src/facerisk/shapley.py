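"""Shapley-value feature attribution with an interventional value function.

The value of a coalition S for sample x is the mean model output over a
background sample with the columns in S replaced by x's values
(marginal/interventional expectation).  Two estimators are provided:

* exact subset enumeration (all 2^p coalitions) for p <= 12 features --
  the oracle, satisfying local accuracy, symmetry and dummy exactly;
* antithetic permutation sampling at scale, with a Monte-Carlo standard
  error reported per attribution.

Pairwise Shapley interaction indices are computed by exact enumeration
over coalitions excluding the pair; the diagonal holds the main effects
(phi_i minus the off-diagonal row sum), so interaction rows sum back to
the per-feature attributions exactly.

Explanations default to probability space for cross-model comparability;
margin space is available where the model exposes one.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

__all__ = [
    "Attribution",
    "InteractionMatrix",
    "shap_values",
    "mean_abs_ranking",
    "per_sample_decomposition",
    "interaction_values",
]

ENUMERATION_CAP = 12


class CapacityError(ValueError):
    """Exact enumeration requested beyond the subset-enumeration cap."""


@dataclass
class Attribution:
    base_value: float
    phi: pd.DataFrame  # samples x features
    background: pd.DataFrame
    output_space: str = "probability"
    standard_error: pd.DataFrame | None = None
    model_output: np.ndarray | None = None

    def local_accuracy_gap(self) -> np.ndarray:
        """base + sum(phi) minus the model output, per sample."""
        return self.base_value + self.phi.sum(axis=1).to_numpy() - self.model_output


@dataclass
class InteractionMatrix:
    values: np.ndarray  # samples x features x features, symmetric
    features: list[str]

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=2)


# ---------------------------------------------------------------------------
# Model plumbing
# ---------------------------------------------------------------------------


def _as_predict_fn(model, output: str):
    if callable(model) and not hasattr(model, "predict_proba"):
        return model
    est = getattr(model, "estimator", model)
    features = getattr(model, "features", None)

    def fn(X: np.ndarray) -> np.ndarray:
        if features is not None and isinstance(X, np.ndarray):
            X = pd.DataFrame(X, columns=features)
        if output == "probability":
            return np.asarray(est.predict_proba(X))[:, 1]
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(X))
        from scipy.special import logit

        p = np.clip(np.asarray(est.predict_proba(X))[:, 1], 1e-12, 1 - 1e-12)
        return logit(p)

    return fn


def _tables(X, background) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xv.shape[1])]
    bg = background.to_numpy(dtype=float) if isinstance(background, pd.DataFrame) else np.asarray(background, dtype=float)
    if bg.ndim != 2 or bg.shape[0] == 0:
        raise ValueError("background must be a non-empty 2-D table")
    if bg.shape[1] != Xv.shape[1]:
        raise ValueError("background and X must share the feature schema")
    return Xv, bg, names


def _coalition_values(fn, Xv: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """val[mask, i] = E_bg f(x_i with coalition `mask` columns from x_i)."""
    n, p = Xv.shape
    b = bg.shape[0]
    vals = np.empty((2 ** p, n))
    for mask in range(2 ** p):
        cols = [j for j in range(p) if mask >> j & 1]
        comp = np.repeat(bg[None, :, :], n, axis=0)  # n x b x p
        comp[:, :, cols] = Xv[:, None, cols]
        out = fn(comp.reshape(n * b, p))
        vals[mask] = out.reshape(n, b).mean(axis=1)
    return vals


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------


def _exact_phi(fn, Xv: np.ndarray, bg: np.ndarray) -> np.ndarray:
    n, p = Xv.shape
    vals = _coalition_values(fn, Xv, bg)
    w = np.array([factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)])
    phi = np.zeros((n, p))
    for mask in range(2 ** p):
        s = bin(mask).count("1")
        for j in range(p):
            if not mask >> j & 1:
                phi[:, j] += w[s] * (vals[mask | (1 << j)] - vals[mask])
    return phi


def _sampled_phi(
    fn, Xv: np.ndarray, bg: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n, p = Xv.shape
    b = bg.shape[0]
    estimates = np.zeros((n_permutations, n, p))
    base = np.repeat(bg[None, :, :], n, axis=0)
    for r in range(n_permutations):
        perm = rng.permutation(p)
        if r % 2 == 1:  # antithetic partner of the previous draw
            perm = prev_perm[::-1]
        prev_perm = perm
        comp = base.copy()
        prev_vals = fn(comp.reshape(n * b, p)).reshape(n, b).mean(axis=1)
        for j in perm:
            comp[:, :, j] = Xv[:, None, j]
            new_vals = fn(comp.reshape(n * b, p)).reshape(n, b).mean(axis=1)
            estimates[r, :, j] = new_vals - prev_vals
            prev_vals = new_vals
    phi = estimates.mean(axis=0)
    se = estimates.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return phi, se


def shap_values(
    model,
    X,
    background,
    mode: str = "auto",
    output: str = "probability",
    n_permutations: int = 256,
    seed: int = 0,
) -> Attribution:
    """Interventional Shapley values for every row of X.

    ``mode``: 'exact' (enumeration, p <= 12), 'sampling', or 'auto'
    (exact when the feature count permits).
    """
    fn = _as_predict_fn(model, output)
    Xv, bg, names = _tables(X, background)
    p = Xv.shape[1]
    if mode == "auto":
        mode = "exact" if p <= ENUMERATION_CAP else "sampling"
    if mode == "exact" and p > ENUMERATION_CAP:
        raise CapacityError(f"exact enumeration capped at {ENUMERATION_CAP} features, got {p}")
    base_value = float(np.mean(fn(bg)))
    se_frame = None
    if mode == "exact":
        phi = _exact_phi(fn, Xv, bg)
    else:
        rng = np.random.default_rng(seed)
        phi, se = _sampled_phi(fn, Xv, bg, n_permutations, rng)
        se_frame = pd.DataFrame(se, columns=names)
    return Attribution(
        base_value=base_value,
        phi=pd.DataFrame(phi, columns=names),
        background=pd.DataFrame(bg, columns=names),
        output_space=output,
        standard_error=se_frame,
        model_output=fn(Xv),
    )


def mean_abs_ranking(attr: Attribution) -> pd.DataFrame:
    """Features ordered by descending mean |phi| (name breaks ties)."""
    mean_abs = attr.phi.abs().mean(axis=0)
    out = (
        pd.DataFrame({"feature": mean_abs.index, "mean_abs_phi": mean_abs.to_numpy()})
        .sort_values(["mean_abs_phi", "feature"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def per_sample_decomposition(attr: Attribution, i: int) -> pd.DataFrame:
    """Waterfall data: contributions sorted by |phi|, cumulative from base."""
    row = attr.phi.iloc[i]
    order = row.abs().sort_values(ascending=False, kind="mergesort").index
    contrib = row[order]
    cumulative = attr.base_value + contrib.cumsum()
    return pd.DataFrame(
        {"feature": order, "phi": contrib.to_numpy(), "cumulative": cumulative.to_numpy()}
    )


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------


def interaction_values(
    model,
    X,
    background,
    output: str = "probability",
) -> InteractionMatrix:
    """Pairwise Shapley interaction indices by exact enumeration (p <= 12).

    Off-diagonal entries hold half the total (i, j) interaction each so the
    matrix is symmetric; the diagonal is the main effect phi_i minus the
    off-diagonal row sum, making each row sum to phi_i.
    """
    fn = _as_predict_fn(model, output)
    Xv, bg, names = _tables(X, background)
    n, p = Xv.shape
    if p > ENUMERATION_CAP:
        raise CapacityError(f"exact interactions capped at {ENUMERATION_CAP} features, got {p}")
    vals = _coalition_values(fn, Xv, bg)
    phi = np.zeros((n, p))
    w1 = np.array([factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)])
    for mask in range(2 ** p):
        s = bin(mask).count("1")
        for j in range(p):
            if not mask >> j & 1:
                phi[:, j] += w1[s] * (vals[mask | (1 << j)] - vals[mask])
    inter = np.zeros((n, p, p))
    if p >= 2:
        w2 = np.array(
            [factorial(s) * factorial(p - s - 2) / factorial(p - 1) for s in range(p - 1)]
        )
        for i_f in range(p):
            for j_f in range(i_f + 1, p):
                bi, bj = 1 << i_f, 1 << j_f
                for mask in range(2 ** p):
                    if mask & (bi | bj):
                        continue
                    s = bin(mask).count("1")
                    delta = (
                        vals[mask | bi | bj] - vals[mask | bi] - vals[mask | bj] + vals[mask]
                    )
                    inter[:, i_f, j_f] += 0.5 * w2[s] * delta
                inter[:, j_f, i_f] = inter[:, i_f, j_f]
    for j in range(p):
        inter[:, j, j] = phi[:, j] - (inter[:, j, :].sum(axis=1) - inter[:, j, j])
    return InteractionMatrix(inter, names)
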