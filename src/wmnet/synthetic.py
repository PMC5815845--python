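"""Synthetic datasets with planted ground truth.

The generator emulates the statistical structure the decomposition pipeline
assumes: each subject's contrast map is a linear mixture of k sparse
super-Gaussian (Laplace) spatial sources with subject-wise mixing scores,
plus a common task-activation mean map, additive per-voxel batch offsets,
and Gaussian noise.  Behavioral variables and region-wise FA values are tied
to chosen component scores with stated standardized slopes; everything else
is independent noise with realistic marginals.  All output is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.vq import kmeans2

from .behavior import TaskSchedule, ResponseLog
from .containers import ContrastMatrix, ProbabilisticAtlas, SyntheticGroundTruth
from .errors import InvalidConfigError

BEHAVIOR_VARIABLES = [
    "d_prime_2back",
    "d_prime_0back",
    "rt_difference",
    "episodic_memory",
    "item_familiarity",
]

#: Affine (location, scale) transforms giving the latent standard-normal
#: behavioral variables marginals close to the study's reported ranges.
_BEHAVIOR_MARGINALS = {
    "d_prime_2back": (2.53, 0.80),
    "d_prime_0back": (3.65, 0.50),
    "rt_difference": (126.15, 100.0),
    "episodic_memory": (30.77, 8.0),
    "item_familiarity": (3.53, 10.0),
}


@dataclass
class SyntheticConfig:
    """Study-condition parameters for one synthetic dataset.

    ``batch_levels`` lists (n_levels, offset_sd) per batch factor, default
    mirroring the study's hardware (3 levels), software (2) and processing
    (2) batches.  ``behavioral_effects`` lists (component index, variable
    name, standardized slope); ``fa_effect`` is (component index, region
    indices, standardized slope).  ``activation_effect`` is the group-mean
    task activation inside the active region in Cohen's-d units; it is what
    makes the working-memory-network mask non-empty downstream.
    """

    n_subjects: int = 300
    grid_dims: tuple[int, int, int] = (16, 16, 16)
    n_components_true: int = 4
    source_sparsity: float = 0.08
    source_patches: int = 4
    source_distribution: str = "laplace"
    noise_sd: float = 0.5
    batch_levels: tuple[tuple[int, float], ...] = ((3, 0.3), (2, 0.3), (2, 0.3))
    behavioral_effects: tuple = (
        (0, "d_prime_2back", 0.24),
        (1, "d_prime_0back", 0.25),
    )
    fa_effect: tuple | None = (0, (0, 1, 2), 0.15)
    n_fa_regions: int = 70
    n_atlas_regions: int = 20
    activation_effect: float = 0.5
    active_fraction: float = 0.5
    missing_rate: float = 0.0
    n_high_missing_subjects: int = 0
    seed: int = 0

    def validate(self) -> None:
        n_voxels = int(np.prod(self.grid_dims))
        if self.n_components_true < 1:
            raise InvalidConfigError("need at least one component")
        if self.n_components_true > min(self.n_subjects, n_voxels):
            raise InvalidConfigError("k_true exceeds min(n_subjects, n_voxels)")
        if not (0 < self.source_sparsity <= 1):
            raise InvalidConfigError("source_sparsity must be in (0, 1]")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")
        for c, var, slope in self.behavioral_effects:
            if abs(slope) > 1:
                raise InvalidConfigError(f"slope for {var} outside [-1, 1]")
            if c >= self.n_components_true:
                raise InvalidConfigError(f"behavioral effect on unknown component {c}")
        if self.fa_effect is not None:
            c, regions, slope = self.fa_effect
            if abs(slope) > 1:
                raise InvalidConfigError("FA slope outside [-1, 1]")
            if c >= self.n_components_true:
                raise InvalidConfigError("FA effect on unknown component")
        if self.source_distribution != "laplace":
            raise InvalidConfigError("only the Laplace source family is implemented")


def _zscore_rows(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)


def _zscore_cols(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=0, keepdims=True)) / a.std(axis=0, keepdims=True)


def _grid_coords(grid_dims) -> np.ndarray:
    return np.indices(grid_dims).reshape(3, -1).T


def _active_region(grid_dims, fraction: float) -> np.ndarray:
    """Central ellipsoid covering approximately ``fraction`` of the grid."""
    coords = _grid_coords(grid_dims).astype(float)
    center = (np.asarray(grid_dims) - 1) / 2.0
    radii = np.asarray(grid_dims) / 2.0
    d2 = (((coords - center) / radii) ** 2).sum(axis=1)
    cut = np.quantile(d2, fraction)
    return d2 <= cut


def _patchy_support(rng, coords, active_idx, n_support, n_patches):
    """Support set grown as compact spherical patches around random foci."""
    n_patches = max(1, min(n_patches, n_support))
    centers = coords[rng.choice(active_idx, size=n_patches, replace=False)]
    active_coords = coords[active_idx]
    # distance of every active voxel to its nearest focus
    d2 = np.min(
        ((active_coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    # deterministic tie-break, random within equal distances
    order = np.lexsort((rng.random(len(active_idx)), d2))
    return active_idx[order[:n_support]]


def _effect_variable(rng, scores, effects, n):
    """Standard-normal variable with planted standardized slopes on scores."""
    total = sum(slope**2 for _, slope in effects)
    if total > 1:
        raise InvalidConfigError("sum of squared slopes exceeds 1 for one variable")
    y = np.zeros(n)
    for comp, slope in effects:
        y += slope * scores[:, comp]
    y += np.sqrt(1.0 - total) * rng.standard_normal(n)
    return y


def generate_atlas(
    grid_dims, n_regions: int = 20, seed: int = 0, sigma: float = 2.5
) -> ProbabilisticAtlas:
    """Probabilistic atlas of smoothed blob regions, per-voxel sums <= 1.

    Region centers are spread by k-means over the voxel grid, each region is
    a Gaussian blob of width ``sigma`` voxels, and voxels where blobs overlap
    beyond total probability 1 are renormalized.
    """
    coords = _grid_coords(grid_dims).astype(float)
    n_voxels = len(coords)
    if n_regions < 1 or n_regions > n_voxels:
        raise InvalidConfigError("n_regions must be in [1, n_voxels]")
    rng = np.random.default_rng(seed)
    centers, _ = kmeans2(coords, n_regions, minit="++", seed=rng)
    d2 = ((coords[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2)
    prob = np.exp(-d2 / (2.0 * sigma**2))
    total = prob.sum(axis=0)
    over = total > 1.0
    prob[:, over] /= total[over]
    names = [f"region{i:02d}" for i in range(n_regions)]
    return ProbabilisticAtlas(
        region_names=names,
        probability_maps=prob,
        voxel_coordinates=coords.astype(int),
        grid_dims=tuple(grid_dims),
    )


def generate_dataset(config: SyntheticConfig):
    """Generate one dataset: (ContrastMatrix, behavior table, FA table,
    ProbabilisticAtlas, SyntheticGroundTruth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_subjects
    n = int(np.prod(config.grid_dims))
    k = config.n_components_true
    coords = _grid_coords(config.grid_dims)

    active = _active_region(config.grid_dims, config.active_fraction)
    active_idx = np.flatnonzero(active)

    # Sparse Laplace sources on compact patchy supports inside the active
    # region (brain networks are a few contiguous foci, not scattered
    # voxels), z-scaled over all voxels.
    n_support = max(1, int(round(config.source_sparsity * n)))
    S = np.zeros((k, n))
    for c in range(k):
        support = _patchy_support(
            rng, coords, active_idx, min(n_support, len(active_idx)), config.source_patches
        )
        S[c, support] = rng.laplace(0.0, 1.0, size=len(support))
    S = _zscore_rows(S)

    A = _zscore_cols(rng.standard_normal((m, k)))

    # Batch factors: additive per-voxel offsets drawn once per level.
    batch = {}
    batch_signal = np.zeros((m, n))
    for f, (levels, mag) in enumerate(config.batch_levels):
        assign = rng.integers(0, levels, size=m)
        offsets = rng.normal(0.0, mag, size=(levels, n))
        batch_signal += offsets[assign]
        batch[f"batch{f}"] = assign
    batch_df = pd.DataFrame(batch)

    sd_total = np.sqrt((S**2).sum(axis=0) + config.noise_sd**2)
    mean_map = config.activation_effect * sd_total * active

    values = mean_map + A @ S + batch_signal
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=(m, n))

    missing = np.zeros((m, n), dtype=bool)
    if config.missing_rate > 0:
        missing |= rng.random((m, n)) < config.missing_rate
    if config.n_high_missing_subjects > 0:
        subs = rng.choice(m, size=config.n_high_missing_subjects, replace=False)
        for s in subs:
            missing[s, rng.random(n) < 0.5] = True
    values = values.copy()
    values[missing] = np.nan

    contrast = ContrastMatrix(
        values=values,
        coords=coords,
        missing=missing,
        grid_dims=tuple(config.grid_dims),
    )

    behavior = _generate_behavior(rng, A, config)
    fa = _generate_fa(rng, A, config)
    atlas = generate_atlas(
        config.grid_dims,
        n_regions=config.n_atlas_regions,
        seed=int(rng.integers(2**31 - 1)),
    )
    truth = SyntheticGroundTruth(
        true_sources=S,
        true_scores=A,
        batch_assignments=batch_df,
        planted_effects={
            "behavioral_effects": list(config.behavioral_effects),
            "fa_effect": config.fa_effect,
        },
        active_mask=active,
        mean_map=mean_map,
        seed=config.seed,
    )
    return contrast, behavior, fa, atlas, truth


def _generate_behavior(rng, A, config) -> pd.DataFrame:
    m = config.n_subjects
    effects_by_var: dict[str, list] = {v: [] for v in BEHAVIOR_VARIABLES}
    for comp, var, slope in config.behavioral_effects:
        if var not in effects_by_var:
            raise InvalidConfigError(f"unknown behavioral variable {var!r}")
        effects_by_var[var].append((comp, slope))

    latent = {
        var: _effect_variable(rng, A, effects_by_var[var], m) for var in BEHAVIOR_VARIABLES
    }
    table = {
        var: loc + scale * latent[var]
        for var, (loc, scale) in _BEHAVIOR_MARGINALS.items()
    }
    table["d_prime_difference"] = table["d_prime_2back"] - table["d_prime_0back"]

    # Covariates with realistic marginals and no planted effects.
    table["sex"] = (rng.random(m) < 0.614).astype(int)  # 1 = female
    table["age"] = rng.integers(18, 36, size=m)
    table["hand"] = (rng.random(m) < 0.903).astype(int)  # 1 = right
    table["motivation"] = rng.choice([1, 2, 3, 4, 5], size=m, p=[0.0, 0.005, 0.066, 0.444, 0.485])
    table["difficulty"] = rng.choice([1, 2, 3, 4, 5], size=m, p=[0.092, 0.403, 0.381, 0.121, 0.003])
    table["smoking"] = rng.choice([1, 2, 3, 4, 5], size=m, p=[0.65, 0.23, 0.052, 0.068, 0.0])
    table["sleep"] = np.clip(rng.normal(7.96, 1.1, size=m), 3.75, 12.0)
    table["chronotype"] = (rng.random(m) < 0.698).astype(int)  # 1 = eveningness
    table["bmi"] = np.clip(rng.normal(22.19, 2.7, size=m), 16.0, 37.0)
    table["icv"] = rng.normal(1.5e6, 1.5e5, size=m)
    df = pd.DataFrame(table)
    df.insert(0, "subject", np.arange(m))
    return df


def _generate_fa(rng, A, config) -> pd.DataFrame:
    """70 region columns named wm{base:02d}_{lh,rh}; FA on a realistic scale.

    Latent values are standard normal with planted slopes; the affine map to
    mean 0.45, sd 0.05 (clipped to [0, 1]) keeps all correlations intact.
    """
    m = config.n_subjects
    R = config.n_fa_regions
    Z = rng.standard_normal((m, R))
    if config.fa_effect is not None:
        comp, regions, slope = config.fa_effect
        for r in regions:
            Z[:, r] = slope * A[:, comp] + np.sqrt(1 - slope**2) * rng.standard_normal(m)
    fa = np.clip(0.45 + 0.05 * Z, 0.0, 1.0)
    names = [f"wm{i // 2:02d}_{'lh' if i % 2 == 0 else 'rh'}" for i in range(R)]
    df = pd.DataFrame(fa, columns=names)
    df.insert(0, "subject", np.arange(m))
    return df


def generate_trial_responses(
    schedule: TaskSchedule,
    d_prime: float | dict,
    criterion: float = 0.0,
    miss_rate: float = 0.0,
    seed: int = 0,
) -> ResponseLog:
    """Equal-variance signal-detection responder on a task schedule.

    Each stimulus is missing with probability ``miss_rate``; otherwise the
    response is "target" with probability Phi(d'/2 - c) for targets and
    Phi(-d'/2 - c) for nontargets.  ``d_prime`` may be a scalar or a mapping
    from condition name to d'.
    """
    if not (0.0 <= miss_rate <= 1.0):
        raise ValueError("miss_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    conds = schedule.trials["condition"].to_numpy()
    is_target = schedule.trials["is_target"].to_numpy()
    if not isinstance(d_prime, dict):
        d_prime = {c: d_prime for c in np.unique(conds)}
    dvec = np.array([d_prime[c] for c in conds], dtype=float)
    p_target = np.where(
        is_target,
        stats.norm.cdf(dvec / 2.0 - criterion),
        stats.norm.cdf(-dvec / 2.0 - criterion),
    )
    resp = np.where(rng.random(len(conds)) < p_target, "target", "nontarget")
    missing = rng.random(len(conds)) < miss_rate
    resp = np.where(missing, "missing", resp)
    rt = np.where(missing, np.nan, np.clip(rng.normal(500.0, 120.0, len(conds)), 150, None))
    return ResponseLog(pd.DataFrame({"response": resp, "rt_ms": rt}))
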