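"""Shared data containers for the pipeline.

Tabular data (behavior, FA) travels as plain :class:`pandas.DataFrame`
objects; the containers here hold the array-valued objects that need voxel
bookkeeping (coordinates, affines, masks) or provenance (seeds, convergence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ContrastMatrix:
    """Subjects x voxels matrix of 2-back - 0-back contrast estimates.

    ``values`` is (n_subjects, n_voxels); ``coords`` holds the integer ijk
    triple of every column; ``missing`` marks unavailable voxel estimates.
    """

    values: np.ndarray
    coords: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    missing: np.ndarray | None = None
    subject_ids: list | None = None
    grid_dims: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x voxels)")
        if self.coords.shape != (self.values.shape[1], 3):
            raise ValueError("coords must be (n_voxels, 3)")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValueError("missing mask must match values shape")
        if self.subject_ids is None:
            self.subject_ids = list(range(self.values.shape[0]))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def subset_voxels(self, keep: np.ndarray) -> "ContrastMatrix":
        keep = np.asarray(keep)
        return ContrastMatrix(
            values=self.values[:, keep],
            coords=self.coords[keep],
            affine=self.affine,
            missing=None if self.missing is None else self.missing[:, keep],
            subject_ids=list(self.subject_ids),
            grid_dims=self.grid_dims,
        )

    def subset_subjects(self, keep: np.ndarray) -> "ContrastMatrix":
        keep = np.asarray(keep)
        return ContrastMatrix(
            values=self.values[keep],
            coords=self.coords,
            affine=self.affine,
            missing=None if self.missing is None else self.missing[keep],
            subject_ids=[self.subject_ids[i] for i in np.atleast_1d(keep)],
            grid_dims=self.grid_dims,
        )


@dataclass
class WMNMask:
    """Voxelwise group statistics and the working-memory-network mask."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    in_mask: np.ndarray
    df: int
    alpha: float
    zero_variance: np.ndarray


@dataclass
class ProbabilisticAtlas:
    """Population-style probabilistic parcellation on a voxel grid.

    ``probability_maps`` is (n_regions, n_voxels); per-voxel probabilities sum
    to at most 1.
    """

    region_names: list[str]
    probability_maps: np.ndarray
    voxel_coordinates: np.ndarray
    grid_dims: tuple[int, int, int]

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def to_4d(self) -> np.ndarray:
        out = np.zeros((self.n_regions, *self.grid_dims))
        i, j, k = self.voxel_coordinates.T
        out[:, i, j, k] = self.probability_maps
        return out


@dataclass
class ICADecomposition:
    """Spatial ICA result: z-scaled voxel loadings and subject scores.

    ``sources`` is (k, n_voxels); ``scores`` (mixing coefficients) is
    (n_subjects, k); reconstruction holds in the retained PCA subspace as
    scores @ sources ~= per-subject standardized data.
    """

    sources: np.ndarray
    scores: np.ndarray
    k: int
    eigenvalues: np.ndarray
    seed: int
    tolerance: float
    max_iterations: int
    n_iterations: int
    converged: bool
    nonlinearity: str = "logcosh"

    def copy(self) -> "ICADecomposition":
        return ICADecomposition(
            sources=self.sources.copy(),
            scores=self.scores.copy(),
            k=self.k,
            eigenvalues=self.eigenvalues.copy(),
            seed=self.seed,
            tolerance=self.tolerance,
            max_iterations=self.max_iterations,
            n_iterations=self.n_iterations,
            converged=self.converged,
            nonlinearity=self.nonlinearity,
        )


@dataclass
class SyntheticGroundTruth:
    """Planted quantities behind one synthetic dataset."""

    true_sources: np.ndarray
    true_scores: np.ndarray
    batch_assignments: "object"  # DataFrame, one column per batch factor
    planted_effects: dict
    active_mask: np.ndarray
    mean_map: np.ndarray
    seed: int
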