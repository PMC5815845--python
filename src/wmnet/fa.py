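"""Associations of component scores with white-matter microstructure.

Per white-matter region, the component's subject scores are regressed on the
region's mean fractional anisotropy (FA) with sex, age, handedness,
intracranial volume and the remaining components' scores as covariates.  Two
global tests summarize the 70 region p-values per component: a
Kolmogorov-Smirnov test against the uniform distribution expected under the
null, and an empirical p based on the count of nominally significant regions
under permutation of the component scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import linmod
from .errors import DegenerateInputError
from .groupmask import bh_fdr


def _covariate_design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    cols = [np.ones(n)]
    for c in covariates.columns:
        v = covariates[c].to_numpy(dtype=float)
        if v.std(ddof=1) == 0:
            raise DegenerateInputError(f"constant covariate {c!r}")
        cols.append(linmod.zscore(v))
    return np.column_stack(cols)


def _fwl_blocks(scores, fa_table, covariates):
    """Residualize the z-scored outcome and every z-scored FA column on the
    covariate design (Frisch-Waugh-Lovell); exact for the full OLS fit."""
    y = linmod.zscore(np.asarray(scores, dtype=float))
    n = len(y)
    regions = [c for c in fa_table.columns if c != "subject"]
    F = np.empty((n, len(regions)))
    for j, c in enumerate(regions):
        v = fa_table[c].to_numpy(dtype=float)
        if v.std(ddof=1) == 0:
            raise DegenerateInputError(f"constant FA column {c!r}")
        F[:, j] = linmod.zscore(v)
    C = _covariate_design(covariates, n)
    M = linmod.residual_projector(C)
    # df: n - (covariates incl. intercept) - 1 FA predictor
    df = n - C.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough subjects for the covariate design")
    return y, M @ y[:, None], M @ F, regions, M, df


def fit_fa_models(
    scores: np.ndarray,
    fa_table: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    apply_fdr: bool = True,
) -> pd.DataFrame:
    """Standardized beta and two-sided p per FA region.

    The rows supplied in ``fa_table`` define the FDR family (e.g. three
    hemisphere scopes x 70 regions when the caller stacks scopes).
    """
    _, ry, RF, regions, _, df = _fwl_blocks(scores, fa_table, covariates)
    beta, t, p = linmod.partial_corr_t(ry[:, 0], RF, df)
    out = pd.DataFrame({"region": regions, "beta": beta, "t": t, "df": df, "p": p})
    if apply_fdr:
        out["q"], _ = bh_fdr(out["p"].to_numpy(), alpha)
    return out


def hemisphere_scopes(fa_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split ``*_lh`` / ``*_rh`` columns into both/left/right scope tables;
    the "both" scope averages the two hemispheres per region."""
    lh = sorted(c for c in fa_table.columns if c.endswith("_lh"))
    rh = sorted(c for c in fa_table.columns if c.endswith("_rh"))
    bases = sorted({c[:-3] for c in lh} & {c[:-3] for c in rh})
    both = pd.DataFrame(
        {b: (fa_table[b + "_lh"] + fa_table[b + "_rh"]) / 2.0 for b in bases}
    )
    return {
        "both": both,
        "left": fa_table[[b + "_lh" for b in bases]],
        "right": fa_table[[b + "_rh" for b in bases]],
    }


def ks_uniformity(p_values: np.ndarray, mode: str = "asymp"):
    """Two-sided one-sample KS statistic of p-values against Uniform(0, 1).

    A component whose 70 region p-values pile up near zero yields a large D;
    under the global null D is small and its own p is uniform.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    res = stats.kstest(p, "uniform", method=mode)
    return float(res.statistic), float(res.pvalue)


def empirical_fa_p(
    scores: np.ndarray,
    fa_table: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Empirical p for the count of nominally significant FA regions.

    The component's scores are permuted across subjects (covariates stay
    attached to their subjects) and the regions with nominal p < alpha are
    recounted per permutation; p = (1 + #{null count >= observed}) /
    (n_perm + 1).  Permuting only the outcome leaves the covariate
    projection unchanged, so the FWL blocks are reused across permutations
    (exactly equivalent to refitting every model).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1 (null undefined otherwise)")
    y, ry, RF, regions, M, df = _fwl_blocks(scores, fa_table, covariates)
    _, t_obs, p_obs = linmod.partial_corr_t(ry[:, 0], RF, df)
    observed = int((p_obs < alpha).sum())
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)

    rng = np.random.default_rng(seed)
    xn = np.linalg.norm(RF, axis=0)
    null_counts = np.zeros(n_perm, dtype=int)
    block = 256  # permutations per matmul block
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        Yp = np.column_stack([y[rng.permutation(len(y))] for _ in range(b)])
        RYP = M @ Yp  # (n, b)
        yn = np.linalg.norm(RYP, axis=0)
        r = np.clip((RF.T @ RYP) / (xn[:, None] * yn[None, :]), -1.0, 1.0)
        t_null = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
        null_counts[done : done + b] = (np.abs(t_null) > t_crit).sum(axis=0)
        done += b
    emp_p = (1.0 + (null_counts >= observed).sum()) / (n_perm + 1.0)
    return observed, float(emp_p), null_counts


def fa_component_summary(
    score_matrix: np.ndarray,
    fa_table: pd.DataFrame,
    covariates_base: pd.DataFrame | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-component global FA association: KS uniformity and empirical p,
    each BH-FDR-corrected over components.

    ``score_matrix`` is (n_subjects, k); for each component the remaining
    components' scores are appended to the covariates.
    """
    score_matrix = np.asarray(score_matrix, dtype=float)
    k = score_matrix.shape[1]
    rows = []
    for c in range(k):
        cov = pd.DataFrame(
            {f"ic{j}": score_matrix[:, j] for j in range(k) if j != c}
        )
        if covariates_base is not None:
            for name in covariates_base.columns:
                cov[name] = covariates_base[name].to_numpy(dtype=float)
        fits = fit_fa_models(score_matrix[:, c], fa_table, cov, alpha, apply_fdr=False)
        D, ks_p = ks_uniformity(fits["p"].to_numpy())
        observed, emp_p, _ = empirical_fa_p(
            score_matrix[:, c], fa_table, cov, n_perm=n_perm, seed=seed + c, alpha=alpha
        )
        rows.append(
            {
                "component": c,
                "ks_D": D,
                "ks_p": ks_p,
                "n_nominal_significant": observed,
                "empirical_p": emp_p,
            }
        )
    out = pd.DataFrame(rows)
    out["ks_q"], _ = bh_fdr(out["ks_p"].to_numpy(), alpha)
    out["empirical_q"], _ = bh_fdr(out["empirical_p"].to_numpy(), alpha)
    return out
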