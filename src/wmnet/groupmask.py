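"""Working-memory-network mask: group statistics over contrast maps.

The mask is the set of voxels significantly more active under the 2-back
than the 0-back condition: one-sample t tests per voxel, Benjamini-Hochberg
FDR at alpha = 0.05, restricted to positive t.  Subjects with extreme
missing-voxel counts are dropped first, then every voxel with any remaining
missing value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ContrastMatrix, WMNMask
from .errors import EmptyMaskError


def missing_data_filter(cm: ContrastMatrix, sd_threshold: float = 4.0) -> ContrastMatrix:
    """Drop subjects whose missing-voxel count exceeds mean + 4 SD (computed
    once over all subjects), then drop every voxel still missing anywhere."""
    if cm.missing is None or not cm.missing.any():
        return cm
    counts = cm.missing.sum(axis=1)
    mu, sd = counts.mean(), counts.std(ddof=1)
    keep_subjects = np.flatnonzero(counts <= mu + sd_threshold * sd)
    out = cm.subset_subjects(keep_subjects)
    keep_voxels = np.flatnonzero(~out.missing.any(axis=0))
    if keep_voxels.size == 0:
        raise EmptyMaskError("all voxels carry missing values")
    return out.subset_voxels(keep_voxels)


def one_sample_t_map(X: np.ndarray | ContrastMatrix):
    """Per-voxel one-sample t against 0 with two-sided p; df = m - 1.

    Zero-variance voxels are flagged; their p is NaN.
    """
    values = X.values if isinstance(X, ContrastMatrix) else np.asarray(X, dtype=float)
    m = values.shape[0]
    if m < 2:
        raise ValueError("need at least two subjects")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(m))
    df = m - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    t[zero_var] = np.nan
    p[zero_var] = np.nan
    return t, p, df, zero_var


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment; reject iff q <= alpha.

    NaN entries are passed through as NaN and never rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    q = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        rej, qv, *_ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = qv
        reject[ok] = qv <= alpha
    return q, reject


def define_wmn_mask(t: np.ndarray, q: np.ndarray, alpha: float = 0.05, p=None, df=None,
                    zero_variance=None) -> WMNMask:
    """Mask of 2-back-positive voxels: t > 0 and FDR-adjusted q <= alpha."""
    t = np.asarray(t, dtype=float)
    q = np.asarray(q, dtype=float)
    with np.errstate(invalid="ignore"):
        in_mask = (t > 0) & (q <= alpha)
    in_mask &= np.isfinite(t) & np.isfinite(q)
    return WMNMask(
        t=t,
        p=p if p is not None else np.full_like(t, np.nan),
        q=q,
        in_mask=in_mask,
        df=df if df is not None else -1,
        alpha=alpha,
        zero_variance=zero_variance
        if zero_variance is not None
        else np.zeros(t.shape, dtype=bool),
    )


def build_wmn_mask(cm: ContrastMatrix, alpha: float = 0.05):
    """Convenience: missing-data filter -> t map -> FDR -> mask.

    Returns (WMNMask over the filtered voxel set, filtered ContrastMatrix
    restricted to mask voxels).
    """
    filtered = missing_data_filter(cm)
    t, p, df, zero_var = one_sample_t_map(filtered)
    q, _ = bh_fdr(p, alpha)
    mask = define_wmn_mask(t, q, alpha, p=p, df=df, zero_variance=zero_var)
    if not mask.in_mask.any():
        raise EmptyMaskError("no 2-back-positive FDR-significant voxels")
    return mask, filtered.subset_voxels(np.flatnonzero(mask.in_mask))


@dataclass
class DistributionDiagnostics:
    """Per-subject and per-voxel distribution shape diagnostics."""

    per_subject: pd.DataFrame
    per_voxel: pd.DataFrame


def _diagnose(vectors: np.ndarray, max_shapiro_n: int = 5000) -> pd.DataFrame:
    rows = []
    for v in vectors:
        v = v[np.isfinite(v)]
        if v.size < 3 or np.std(v) == 0:
            rows.append((np.nan, np.nan, np.nan, np.nan, True))
            continue
        if v.size > max_shapiro_n:
            # Shapiro-Wilk is defined for n <= 5000; thin deterministically.
            idx = np.linspace(0, v.size - 1, max_shapiro_n).astype(int)
            sw = stats.shapiro(v[idx])
        else:
            sw = stats.shapiro(v)
        rows.append(
            (
                stats.skew(v),
                stats.kurtosis(v, fisher=False),  # non-excess: normal = 3
                sw.statistic,
                sw.pvalue,
                False,
            )
        )
    return pd.DataFrame(rows, columns=["skewness", "kurtosis", "shapiro_w", "shapiro_p", "undefined"])


def gaussianity_diagnostics(X: np.ndarray | ContrastMatrix) -> DistributionDiagnostics:
    """Skewness, non-excess kurtosis and Shapiro-Wilk W per subject (row) and
    per voxel (column); constant vectors are flagged undefined."""
    values = X.values if isinstance(X, ContrastMatrix) else np.asarray(X, dtype=float)
    return DistributionDiagnostics(
        per_subject=_diagnose(values),
        per_voxel=_diagnose(values.T),
    )
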