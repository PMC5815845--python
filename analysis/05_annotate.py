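#!/usr/bin/env python
"""Annotate supra-threshold component clusters against the probabilistic
atlas and quantify pairwise spatial overlap.

Positive and negative supra-threshold voxels are clustered separately
(26-connectivity), voxels are assigned to their maximum-probability region
subject to the 25% floor, and only regions with more than 10 cluster voxels
are reported.  The overlap analysis sweeps thresholds for the two
performance-relevant components.

Writes annotation and overlap tables under results/annotation/.
"""

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from wmnet import io
from wmnet.annotate import extract_clusters, label_clusters, mask_fraction, overlap_analysis
from wmnet.containers import ProbabilisticAtlas

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "annotation"
K = 4


def load_atlas() -> ProbabilisticAtlas:
    img = nib.load(str(ROOT / "results/data/atlas.nii.gz"))
    data = np.moveaxis(np.asarray(img.dataobj), -1, 0)
    dims = data.shape[1:]
    coords = np.indices(dims).reshape(3, -1).T
    return ProbabilisticAtlas(
        region_names=[f"region{i:02d}" for i in range(data.shape[0])],
        probability_maps=data.reshape(data.shape[0], -1),
        voxel_coordinates=coords,
        grid_dims=dims,
    )


def main() -> None:
    atlas = load_atlas()
    meta = json.loads((ROOT / "results/ica/decomposition.json").read_text())
    thr = meta["threshold_z"]

    tables = []
    supra_masks = {}
    for c in range(K):
        vol = np.asarray(nib.load(str(ROOT / f"results/ica/wmn_ic{c + 1}_loadings.nii.gz")).dataobj)
        for sign, m in (("positive", vol > thr), ("negative", vol < -thr)):
            clusters = extract_clusters(m, connectivity=26)
            tables.append(label_clusters(clusters, atlas, vol, component=c + 1, sign=sign))
        supra_masks[c + 1] = np.abs(vol) > thr

    nonempty = [t for t in tables if len(t)]
    annotation = pd.concat(nonempty, ignore_index=True) if nonempty else tables[0]
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_tsv(annotation, OUT / "cluster_annotation.tsv")
    print(f"|z| > {thr:.2f}: {len(annotation)} reported (cluster, region) pairs "
          f"across {K} components")
    if len(annotation):
        top = annotation.sort_values("n_voxels", ascending=False).iloc[0]
        print(f"largest labeled cluster: component {top.component} ({top.sign}), "
              f"{top.n_voxels} voxels in {top.region} "
              f"({top.percent_of_region:.0f}% of the region)")

    # overlap of the two planted performance components, mapped to estimates
    est_for_planted = {p: e + 1 for e, p in enumerate(meta["estimated_to_planted"])}
    a, b = est_for_planted[0] - 1, est_for_planted[1] - 1
    S = np.stack([
        np.asarray(nib.load(str(ROOT / f"results/ica/wmn_ic{c + 1}_loadings.nii.gz")).dataobj).ravel()
        for c in range(K)
    ])
    wmn = np.asarray(nib.load(str(ROOT / "results/mask/wmn_mask.nii.gz")).dataobj).ravel() > 0
    overlap = overlap_analysis(S, a, b, thresholds=np.linspace(0, 5, 11), wmn_mask=wmn)
    io.write_tsv(overlap, OUT / "overlap_ic_pair.tsv")
    at_thr = overlap_analysis(S, a, b, thresholds=[thr], wmn_mask=wmn).iloc[0]
    print(f"overlap of estimated components {a + 1} and {b + 1} at z > {thr:.2f}: "
          f"both {100 * at_thr.both:.1f}%, only one {100 * (at_thr.only_a + at_thr.only_b):.1f}% "
          f"of WMN voxels")

    frac = mask_fraction(supra_masks[a + 1].ravel() & wmn, wmn)
    print(f"supra-threshold voxels of component {a + 1} inside the WMN: {100 * frac:.0f}%")


if __name__ == "__main__":
    main()
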