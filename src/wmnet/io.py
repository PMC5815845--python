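"""NIfTI and TSV input/output for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import ContrastMatrix, ProbabilisticAtlas


def flat_to_volume(values: np.ndarray, coords: np.ndarray, grid_dims, fill=np.nan):
    """Scatter flat per-voxel values onto a 3-D grid."""
    vol = np.full(tuple(grid_dims), fill, dtype=float)
    i, j, k = np.asarray(coords, dtype=int).T
    vol[i, j, k] = values
    return vol


def write_contrast_stack(cm: ContrastMatrix, path: str | Path) -> None:
    """4-D NIfTI with subject as the 4th axis; missing voxels are NaN."""
    if cm.grid_dims is None:
        raise ValueError("grid_dims required to write a volume")
    data = np.stack(
        [flat_to_volume(cm.values[s], cm.coords, cm.grid_dims) for s in range(cm.n_subjects)],
        axis=-1,
    )
    nib.save(nib.Nifti1Image(data, cm.affine), str(path))


def read_contrast_stack(path: str | Path, mask_path: str | Path | None = None) -> ContrastMatrix:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    coords = np.argwhere(mask)
    values = data[mask].T  # subjects x voxels
    return ContrastMatrix(
        values=values,
        coords=coords,
        affine=img.affine,
        missing=np.isnan(values),
        grid_dims=data.shape[:3],
    )


def write_mask(mask_flat: np.ndarray, coords, grid_dims, affine, path) -> None:
    vol = flat_to_volume(mask_flat.astype(float), coords, grid_dims, fill=0.0)
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def write_component_maps(sources, coords, grid_dims, affine, out_dir, prefix="ic") -> list[Path]:
    """One z-valued loading volume per component."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c, row in enumerate(np.asarray(sources)):
        vol = flat_to_volume(row, coords, grid_dims, fill=0.0)
        p = out_dir / f"{prefix}{c + 1}_loadings.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), str(p))
        paths.append(p)
    return paths


def write_atlas(atlas: ProbabilisticAtlas, path, affine=None) -> None:
    data = np.moveaxis(atlas.to_4d(), 0, -1)
    nib.save(nib.Nifti1Image(data, affine if affine is not None else np.eye(4)), str(path))


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
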