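#!/usr/bin/env python
"""Relate component subject scores (and single voxels) to task performance.

Per component: standardized multiple regression of the subject scores on the
performance measures and covariates, with the remaining components' scores
as additional covariates and BH-FDR over the predictors x components family.
A voxelwise version (no component covariates) maps the univariate
associations.

Writes the component association table and voxelwise maps under
results/associations/.
"""

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from wmnet import io
from wmnet.assoc import collinearity_filter, fdr_across_tests, fit_ic_model, voxelwise_model
from wmnet.behavior import residualize_matrix
from wmnet.groupmask import missing_data_filter

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "associations"
K = 4

PREDICTORS = ["d_prime_2back", "d_prime_0back", "rt_difference",
              "episodic_memory", "item_familiarity"]
COVARIATES = ["sex", "age", "hand", "motivation", "difficulty",
              "smoking", "sleep", "chronotype", "bmi"]


def main() -> None:
    beh = io.read_tsv(ROOT / "results/data/behavior.tsv")
    scores = io.read_tsv(ROOT / "results/ica/subject_scores.tsv")
    meta = json.loads((ROOT / "results/ica/decomposition.json").read_text())

    candidates = beh[PREDICTORS + COVARIATES].astype(float)
    kept = collinearity_filter(candidates, threshold=0.5)
    dropped = sorted(set(candidates.columns) - set(kept))
    print(f"collinearity filter (|r| > 0.5): kept {len(kept)} variables, "
          f"dropped {dropped if dropped else 'none'}")
    kept_predictors = [c for c in kept if c in PREDICTORS]
    kept_covariates = [c for c in kept if c in COVARIATES]

    rows = []
    for c in range(K):
        cov = beh[kept_covariates].astype(float).copy()
        for j in range(K):
            if j != c:
                cov[f"ic{j + 1}"] = scores[f"ic{j + 1}"]
        rows.append(
            fit_ic_model(scores[f"ic{c + 1}"], beh[kept_predictors].astype(float),
                         cov, component=c + 1)
        )
    results = fdr_across_tests(pd.concat(rows, ignore_index=True))
    io.write_tsv(results, OUT / "ic_associations.tsv")
    fam = results.attrs["family_size"]
    print(f"FDR family: {fam} tests "
          f"({fam // K} predictors/covariates x {K} components)")

    sig = results.query("is_predictor and q <= 0.05")
    for _, r in sig.iterrows():
        print(f"  IC{r.component} ~ {r.predictor}: beta = {r.beta:+.2f}, "
              f"q = {r.q:.2g}, R^2 = {100 * r.r2:.1f}%")

    # voxelwise models without component covariates
    cm = io.read_contrast_stack(ROOT / "results/data/contrast_2b_minus_0b.nii.gz",
                                ROOT / "results/data/brain_mask.nii.gz")
    cm = missing_data_filter(cm)
    wmn = np.asarray(nib.load(str(ROOT / "results/mask/wmn_mask.nii.gz")).dataobj) > 0
    keep = wmn[tuple(cm.coords.T)]
    masked = cm.subset_voxels(np.flatnonzero(keep))
    batches = io.read_tsv(ROOT / "results/data/batches.tsv")
    X = residualize_matrix(masked.values, batches, scale=True)
    vw = voxelwise_model(X, beh[kept_predictors + kept_covariates].astype(float))
    print(f"voxelwise: {vw['n_tests']} tests "
          f"({len(vw['predictors'])} predictors x {masked.n_voxels} voxels); "
          f"{int(vw['significant']['d_prime_2back'].sum())} voxels FDR-significant "
          "for D-prime 2-back")
    for name in ("d_prime_2back", "d_prime_0back"):
        vol = io.flat_to_volume(vw["beta"][name], masked.coords, masked.grid_dims)
        nib.save(nib.Nifti1Image(vol, masked.affine),
                 str(OUT / f"beta_{name}.nii.gz"))


if __name__ == "__main__":
    main()
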