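"""Shared ordinary-least-squares machinery.

Every regression in the pipeline (component-score models, voxelwise maps,
FA-region models, cross-validation regressions) reduces to OLS with z-scored
variables.  The implementations here are vectorized over outcomes so that
permutation loops stay cheap; they are cross-checked against statsmodels in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

#: Smallest p-value reported; underflow is clamped here rather than to 0.
P_FLOOR = 1e-300


def zscore(a: np.ndarray, axis: int = 0, ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0, variance 1 along ``axis``.

    Raises :class:`DegenerateInputError` on constant slices.
    """
    a = np.asarray(a, dtype=float)
    mu = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, ddof=ddof, keepdims=True)
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        raise DegenerateInputError("constant (zero-variance) column in z-scoring")
    return (a - mu) / sd


@dataclass
class OLSResult:
    """Coefficients and inference for one or many outcomes.

    Arrays are shaped (n_terms,) for a single outcome and (n_terms, n_outcomes)
    for stacked outcomes.  ``df`` is the residual degrees of freedom.
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    terms: list[str]
    resid: np.ndarray


def design_matrix(columns: dict[str, np.ndarray], add_intercept: bool = True):
    terms = list(columns)
    X = np.column_stack([np.asarray(columns[c], dtype=float) for c in terms])
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        terms = ["intercept"] + terms
    return X, terms


def _check_full_rank(X: np.ndarray, terms: list[str]) -> None:
    # QR diagnostics name the aliased columns instead of a bare LinAlgError.
    r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
    bad = r < max(X.shape) * np.finfo(float).eps * (r.max() if r.size else 1.0)
    if bad.any():
        names = [terms[i] for i in np.flatnonzero(bad)]
        raise np.linalg.LinAlgError(f"singular design; aliased columns: {names}")


def ols(Y: np.ndarray, X: np.ndarray, terms: list[str] | None = None) -> OLSResult:
    """OLS of one or many outcomes on a common design matrix.

    Y : (n,) or (n, n_outcomes); X : (n, n_terms).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    single = Y.ndim == 1
    Ymat = Y[:, None] if single else Y
    n, q = X.shape
    if terms is None:
        terms = [f"x{j}" for j in range(q)]
    if n <= q:
        raise ValueError(f"need n > n_terms, got n={n}, terms={q}")
    _check_full_rank(X, terms)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Ymat)
    resid = Ymat - X @ beta
    df = n - q
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), P_FLOOR, 1.0)
    if single:
        beta, se, t, p, resid = (a[..., 0] for a in (beta, se, t, p, resid))
    return OLSResult(beta=beta, se=se, t=t, p=p, df=df, terms=terms, resid=resid)


def residual_projector(C: np.ndarray) -> np.ndarray:
    """Annihilator matrix M = I - C (C'C)^-1 C' for a covariate block C.

    Used for Frisch-Waugh-Lovell reformulations where the same covariates are
    partialled out of many outcomes (e.g. permutation loops).
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    return np.eye(n) - C @ np.linalg.solve(C.T @ C, C.T)


def partial_corr_t(ry: np.ndarray, RX: np.ndarray, df: int):
    """t statistics from FWL residuals.

    ry : (n,) outcome residualized on covariates; RX : (n, k) predictors
    residualized the same way.  ``df`` must already account for the covariates
    and the predictor itself.  Returns (beta_partial, t, p) where beta_partial
    is the slope of ry on each residualized predictor column.
    """
    ry = np.asarray(ry, dtype=float)
    RX = np.asarray(RX, dtype=float)
    yn = np.linalg.norm(ry)
    xn = np.linalg.norm(RX, axis=0)
    if yn == 0 or np.any(xn == 0):
        raise DegenerateInputError("zero-variance residual in partial correlation")
    r = (RX.T @ ry) / (yn * xn)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), P_FLOOR, 1.0)
    beta = (RX.T @ ry) / xn**2
    return beta, t, p
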