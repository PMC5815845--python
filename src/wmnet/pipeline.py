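"""End-to-end composition of the decomposition pipeline on one dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import residualize_matrix
from .containers import ContrastMatrix
from .groupmask import build_wmn_mask
from .ica import fastica_decompose


def preprocess_masked(X_masked: ContrastMatrix | np.ndarray, batch: pd.DataFrame | None):
    """Batch residualization of the masked matrix.

    With batch factors supplied, every voxel is residualized on the factor
    indicators and rescaled to unit variance ("standardized residuals").
    Without factors the matrix passes through unchanged -- the decomposition
    standardizes per subject itself, and per-voxel rescaling would distort a
    noise-free mixture.
    """
    values = X_masked.values if isinstance(X_masked, ContrastMatrix) else np.asarray(X_masked)
    if batch is None or batch.shape[1] == 0:
        return values
    return residualize_matrix(values, batch, scale=True)


def run_decomposition_pipeline(
    cm: ContrastMatrix,
    k: int,
    seed: int = 0,
    alpha: float = 0.05,
    batch: pd.DataFrame | None = None,
    ica_kwargs: dict | None = None,
):
    """Mask -> residualize -> spatial ICA; returns a result dict."""
    mask, masked = build_wmn_mask(cm, alpha=alpha)
    values = preprocess_masked(masked, batch)
    decomp = fastica_decompose(values, k, seed=seed, **(ica_kwargs or {}))
    return {
        "wmn_mask": mask,
        "masked_contrast": masked,
        "preprocessed": values,
        "decomposition": decomp,
    }
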