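"""Spatial ICA of contrast maps: fixed-point FastICA and score projection.

Orientation: voxels are observations and subjects are variables, so the
estimated sources are spatial maps (statistically independent across voxels)
and the mixing coefficients are per-subject component scores.  The data are
standardized per subject, PCA-whitened to k dimensions, and unmixed with
symmetric (parallel) fixed-point updates under the log-cosh contrast.  The
direction of each component is arbitrary, so after convergence every
component is recoded such that its largest-|loading| voxel loads positively.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .containers import ContrastMatrix, ICADecomposition
from .errors import RankError


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, ContrastMatrix) else np.asarray(X, dtype=float)


def standardize_maps(values: np.ndarray) -> np.ndarray:
    """Center and scale each subject's map (row) across voxels."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    return (values - mu) / sd


def pca_scree(X) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalue spectrum of the between-subject correlation structure.

    Subjects' maps are standardized, then the eigenvalues of their
    correlation matrix (computed across voxel observations) are returned in
    descending order together with cumulative variance fractions.
    """
    values = _as_values(X)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 voxels")
    D = standardize_maps(values).T  # voxels x subjects
    s = np.linalg.svd(D, compute_uv=False)
    n = D.shape[0]
    eig = np.zeros(values.shape[0])
    eig[: s.size] = s**2 / (n - 1)
    cum = np.cumsum(eig) / eig.sum()
    return eig, cum


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    # W <- (W W')^(-1/2) W
    d, E = np.linalg.eigh(W @ W.T)
    return (E * (1.0 / np.sqrt(d))) @ E.T @ W


def _fastica_W(Z: np.ndarray, k: int, rng, tol: float, max_iter: int):
    """Symmetric fixed-point iteration on whitened data Z (n_obs x k)."""
    n = Z.shape[0]
    W = _sym_decorrelate(rng.standard_normal((k, k)))
    for it in range(1, max_iter + 1):
        Y = W @ Z.T  # k x n
        G = np.tanh(Y)
        g_prime_mean = (1.0 - G**2).mean(axis=1)
        W_new = (G @ Z) / n - g_prime_mean[:, None] * W
        W_new = _sym_decorrelate(W_new)
        lim = float(np.max(np.abs(np.abs(np.diag(W_new @ W.T)) - 1.0)))
        W = W_new
        if lim < tol:
            return W, it, True
    return W, max_iter, False


def fastica_decompose(
    X,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 5,
) -> ICADecomposition:
    """FastICA decomposition into k spatial components.

    On non-convergence the fixed-point iteration is restarted with up to
    ``n_restarts`` derived seeds; if none converges the best attempt is
    returned with ``converged=False`` and a warning.
    """
    values = _as_values(X)
    m, n = values.shape
    if k > min(m, n):
        raise RankError(f"k={k} exceeds min(subjects, voxels)={min(m, n)}")
    D = standardize_maps(values).T  # voxels x subjects
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    if s[k - 1] < max(m, n) * np.finfo(float).eps * s[0]:
        raise RankError(f"k={k} exceeds the numerical rank of the data")
    eigenvalues = s**2 / (n - 1)
    Z = U[:, :k] * np.sqrt(n - 1)  # whitened: unit variance across voxels

    ss = np.random.SeedSequence(seed)
    attempt_seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n_restarts)]
    W = n_it = None
    converged = False
    for attempt_seed in attempt_seeds:
        rng = np.random.default_rng(attempt_seed)
        W, n_it, converged = _fastica_W(Z, k, rng, tol, max_iter)
        if converged:
            break
    if not converged:
        warnings.warn("FastICA did not converge within max_iter on any restart", stacklevel=2)

    S = W @ Z.T  # k x voxels; rows ~ mean 0, var 1 already
    S = (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, keepdims=True)
    A = project_scores(S, D.T, standardize=False)  # mixing: subjects x k
    decomp = ICADecomposition(
        sources=S,
        scores=A,
        k=k,
        eigenvalues=eigenvalues,
        seed=seed,
        tolerance=tol,
        max_iterations=max_iter,
        n_iterations=int(n_it),
        converged=bool(converged),
    )
    return enforce_sign_convention(decomp)


def enforce_sign_convention(decomp: ICADecomposition) -> ICADecomposition:
    """Recode components so the largest-|loading| voxel loads positively.

    Flipping a source row together with its score column leaves the
    reconstruction scores @ sources unchanged; the operation is idempotent.
    """
    out = decomp.copy()
    for c in range(out.k):
        peak = np.argmax(np.abs(out.sources[c]))
        if out.sources[c, peak] < 0:
            out.sources[c] *= -1.0
            out.scores[:, c] *= -1.0
    return out


@dataclass
class ThresholdedMap:
    """Supra-threshold voxel masks at a pooled |loading| quantile."""

    threshold: float
    positive: np.ndarray  # (k, n_voxels) bool
    negative: np.ndarray
    fraction_retained: float


def pooled_threshold(S: np.ndarray, fraction: float = 0.10) -> ThresholdedMap:
    """Threshold at the (1 - fraction) quantile of |loadings| pooled over all
    components; per-component masks split by sign.

    With the study's conventions (z-scaled loadings, fraction 0.10) this is
    the |z| > 1.47-style cut: the 10% most extreme absolute loadings.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    S = np.asarray(S, dtype=float)
    if fraction == 1.0:
        thr = 0.0
        retained = np.ones(S.shape, dtype=bool)
    else:
        thr = float(np.quantile(np.abs(S), 1.0 - fraction))
        retained = np.abs(S) > thr
    return ThresholdedMap(
        threshold=thr,
        positive=retained & (S > 0),
        negative=retained & (S < 0),
        fraction_retained=float(retained.mean()),
    )


def project_scores(S: np.ndarray, X_new, standardize: bool = False) -> np.ndarray:
    """Least-squares component scores for new subjects (dual-regression-style
    back-projection).

    Each new subject's map is expressed as a linear combination of the k
    fixed source maps; the returned (n_subjects, k) coefficients minimize the
    squared reconstruction error.  Set ``standardize=True`` to apply the
    training-side per-subject centering/scaling first.
    """
    S = np.asarray(S, dtype=float)
    values = _as_values(X_new)
    if values.ndim == 1:
        values = values[None, :]
    if standardize:
        values = standardize_maps(values)
    k = S.shape[0]
    if np.linalg.matrix_rank(S) < k:
        raise RankError("rank-deficient source matrix in projection")
    coef, *_ = np.linalg.lstsq(S.T, values.T, rcond=None)
    return coef.T
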