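"""Associations of component scores (and voxels) with behavior.

All models are ordinary least squares on z-transformed variables, so the
coefficients are standardized betas.  Component models include the remaining
components' scores as covariates; voxelwise models do not.  Multiple testing
is controlled by Benjamini-Hochberg FDR over the declared family
(predictors x components, or predictors x voxels).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import linmod
from .groupmask import bh_fdr


def collinearity_filter(
    predictors: pd.DataFrame, threshold: float = 0.5, priority: list[str] | None = None
) -> list[str]:
    """Drop the later member (in priority order) of every pair with
    |Pearson r| above the threshold; returns the retained column names."""
    if predictors.shape[1] < 2:
        raise ValueError("need at least two candidate predictors")
    order = priority if priority is not None else list(predictors.columns)
    corr = predictors[order].corr().abs()
    retained: list[str] = []
    for name in order:
        if all(corr.loc[name, kept] <= threshold for kept in retained):
            retained.append(name)
    return retained


def variance_explained(t: float | np.ndarray, df: int) -> float | np.ndarray:
    """Squared partial correlation R^2 = t^2 / (t^2 + df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    t = np.asarray(t, dtype=float)
    r2 = t**2 / (t**2 + df)
    return float(r2) if r2.ndim == 0 else r2


def fit_ic_model(
    scores: np.ndarray,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    component: int | str = 0,
) -> pd.DataFrame:
    """Standardized multiple regression of one component's subject scores on
    behavioral predictors plus covariates (typically the other components'
    scores, sex, age, ...).

    Returns one row per predictor/covariate with beta, t, df, p and the
    squared partial correlation; ``is_predictor`` marks the task-performance
    terms that enter the FDR family.
    """
    cols = {c: predictors[c].to_numpy(dtype=float) for c in predictors.columns}
    n_pred = len(cols)
    if covariates is not None:
        for c in covariates.columns:
            if c in cols:
                raise ValueError(f"duplicate column {c!r}")
            cols[c] = covariates[c].to_numpy(dtype=float)
    y = linmod.zscore(np.asarray(scores, dtype=float))
    Z = {name: linmod.zscore(v) for name, v in cols.items()}
    X, terms = linmod.design_matrix(Z)
    res = linmod.ols(y, X, terms)
    rows = []
    for j, term in enumerate(terms):
        if term == "intercept":
            continue
        rows.append(
            {
                "component": component,
                "predictor": term,
                "is_predictor": j - 1 < n_pred,
                "beta": res.beta[j],
                "t": res.t[j],
                "df": res.df,
                "p": res.p[j],
                "r2": variance_explained(res.t[j], res.df),
                "n": len(y),
            }
        )
    return pd.DataFrame(rows)


def fdr_across_tests(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH adjustment over the full predictor x component family.

    Only rows with ``is_predictor`` (when the column is present) form the
    family; covariate rows get q = NaN.  The family size is recorded.
    """
    results = results.copy()
    in_family = (
        results["is_predictor"].to_numpy()
        if "is_predictor" in results.columns
        else np.ones(len(results), dtype=bool)
    )
    q = np.full(len(results), np.nan)
    qv, _ = bh_fdr(results.loc[in_family, "p"].to_numpy(), alpha)
    q[in_family] = qv
    results["q"] = q
    results.attrs["family_size"] = int(in_family.sum())
    results.attrs["alpha"] = alpha
    return results


def voxelwise_model(
    X_masked: np.ndarray, predictors: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Univariate-outcome voxel maps: each voxel's contrast values regressed
    on the full z-scored predictor set (no component-score covariates).

    Returns per-predictor beta/t/p/q maps, with BH-FDR applied jointly over
    predictors x voxels; ``n_tests`` records the family size.
    """
    X_masked = np.asarray(X_masked, dtype=float)
    Y = linmod.zscore(X_masked, axis=0)
    Z = {c: linmod.zscore(predictors[c].to_numpy(dtype=float)) for c in predictors.columns}
    D, terms = linmod.design_matrix(Z)
    res = linmod.ols(Y, D, terms)
    pred_idx = [j for j, t in enumerate(terms) if t != "intercept"]
    names = [terms[j] for j in pred_idx]
    p_stack = res.p[pred_idx]  # (n_predictors, n_voxels)
    q_flat, reject_flat = bh_fdr(p_stack.ravel(), alpha)
    q_stack = q_flat.reshape(p_stack.shape)
    reject = reject_flat.reshape(p_stack.shape)
    return {
        "predictors": names,
        "beta": {name: res.beta[j] for name, j in zip(names, pred_idx)},
        "t": {name: res.t[j] for name, j in zip(names, pred_idx)},
        "p": {name: res.p[j] for name, j in zip(names, pred_idx)},
        "q": {name: q_stack[i] for i, name in enumerate(names)},
        "significant": {name: reject[i] for i, name in enumerate(names)},
        "df": res.df,
        "n_tests": int(p_stack.size),
    }
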