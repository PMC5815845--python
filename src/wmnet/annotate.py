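"""Cluster extraction, probabilistic-atlas labeling and spatial overlap.

Supra-threshold voxels of each component are grouped into connected clusters
(positive and negative loadings separately), each voxel is assigned to its
maximum-probability atlas region when that probability reaches 25%, and
regions contributing more than 10 voxels to a cluster are reported with the
percentage of the region's labeled voxels they cover.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import ProbabilisticAtlas

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def extract_clusters(mask: np.ndarray, connectivity: int = 26) -> list[np.ndarray]:
    """Partition a 3-D boolean mask into maximal connected components.

    Returns a list of (cluster_size, 3) integer coordinate arrays, largest
    cluster first (size ties broken by first-voxel raster order).
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(mask, structure=structure)
    clusters = [np.argwhere(labels == i) for i in range(1, n + 1)]
    clusters.sort(key=lambda c: (-len(c), tuple(c[0])))
    return clusters


def assign_regions(atlas: ProbabilisticAtlas, probability_floor: float = 0.25):
    """Per-voxel argmax region assignment subject to the probability floor.

    Returns (assignment, max_probability) flat arrays over the atlas voxel
    set; unassigned voxels get -1.  Ties break toward the lower region index.
    """
    prob = atlas.probability_maps
    best = prob.argmax(axis=0)
    best_p = prob[best, np.arange(prob.shape[1])]
    assignment = np.where(best_p >= probability_floor, best, -1)
    return assignment, best_p


def label_clusters(
    clusters: list[np.ndarray],
    atlas: ProbabilisticAtlas,
    loadings: np.ndarray,
    component: int = 0,
    sign: str = "positive",
    probability_floor: float = 0.25,
    min_voxels: int = 10,
) -> pd.DataFrame:
    """Annotate clusters against the atlas.

    ``loadings`` is the component's 3-D loading volume.  Only regions with
    strictly more than ``min_voxels`` cluster voxels are reported.  The
    percentage divides the cluster-and-region voxel count by the region's
    total labeled voxels across the atlas voxel set.  Each row carries the
    cluster's peak voxel (max |loading|) and the region-wise peak voxel.
    """
    loadings = np.asarray(loadings, dtype=float)
    if tuple(atlas.grid_dims) != loadings.shape:
        raise ValueError("atlas grid does not match the loading volume")
    assignment, _ = assign_regions(atlas, probability_floor)
    coords = atlas.voxel_coordinates
    flat_index = {tuple(c): i for i, c in enumerate(coords)}
    region_totals = np.bincount(assignment[assignment >= 0], minlength=atlas.n_regions)

    rows = []
    for cid, cluster in enumerate(clusters):
        vals = loadings[tuple(cluster.T)]
        peak = cluster[np.argmax(np.abs(vals))]
        assigned = np.array([assignment[flat_index[tuple(v)]] for v in cluster])
        for r in np.unique(assigned[assigned >= 0]):
            in_region = cluster[assigned == r]
            count = len(in_region)
            if count <= min_voxels:
                continue
            rvals = loadings[tuple(in_region.T)]
            rpeak = in_region[np.argmax(np.abs(rvals))]
            rows.append(
                {
                    "component": component,
                    "sign": sign,
                    "cluster": cid,
                    "cluster_size": len(cluster),
                    "region": atlas.region_names[r],
                    "n_voxels": count,
                    "percent_of_region": 100.0 * count / region_totals[r],
                    "cluster_peak_x": peak[0],
                    "cluster_peak_y": peak[1],
                    "cluster_peak_z": peak[2],
                    "cluster_peak_loading": loadings[tuple(peak)],
                    "region_peak_x": rpeak[0],
                    "region_peak_y": rpeak[1],
                    "region_peak_z": rpeak[2],
                    "region_peak_loading": loadings[tuple(rpeak)],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "component",
            "sign",
            "cluster",
            "cluster_size",
            "region",
            "n_voxels",
            "percent_of_region",
            "cluster_peak_x",
            "cluster_peak_y",
            "cluster_peak_z",
            "cluster_peak_loading",
            "region_peak_x",
            "region_peak_y",
            "region_peak_z",
            "region_peak_loading",
        ],
    )


def overlap_analysis(
    S: np.ndarray,
    component_a: int,
    component_b: int,
    thresholds: np.ndarray,
    wmn_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fractions of mask voxels loading above each threshold on both, one, or
    neither of two components; the four fractions partition the mask."""
    if component_a == component_b:
        raise ValueError("components must be distinct")
    S = np.asarray(S, dtype=float)
    za, zb = S[component_a], S[component_b]
    if wmn_mask is not None:
        sel = np.asarray(wmn_mask, dtype=bool)
        za, zb = za[sel], zb[sel]
    rows = []
    for t in np.asarray(thresholds, dtype=float):
        a, b = za > t, zb > t
        rows.append(
            {
                "threshold": t,
                "both": float((a & b).mean()),
                "only_a": float((a & ~b).mean()),
                "only_b": float((~a & b).mean()),
                "neither": float((~a & ~b).mean()),
            }
        )
    return pd.DataFrame(rows)


def mask_fraction(map_mask: np.ndarray, reference_mask: np.ndarray) -> float:
    """|map & reference| / |map|: the share of a map's voxels inside a
    reference mask (e.g. external-network voxels contained in the WMN)."""
    map_mask = np.asarray(map_mask, dtype=bool)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if map_mask.shape != reference_mask.shape:
        raise ValueError("masks must share a grid")
    total = map_mask.sum()
    if total == 0:
        raise ValueError("empty map mask: fraction undefined")
    return float((map_mask & reference_mask).sum() / total)
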