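#!/usr/bin/env python
"""Test component scores against region-wise white-matter FA.

Per region and component: standardized regression of the component scores on
the region's mean FA with sex, age, handedness, intracranial volume and the
remaining components' scores as covariates; hemisphere scopes (both/left/
right) form the FDR family.  Per component, two global tests summarize the
region p-values: KS uniformity and a permutation count (scores shuffled,
n_perm reduced to desk scale).

Writes the region table and component summary under results/fa/.
"""

import json
from pathlib import Path

import pandas as pd

from wmnet import io
from wmnet.fa import fa_component_summary, fit_fa_models, hemisphere_scopes
from wmnet.groupmask import bh_fdr

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "fa"
K = 4
N_PERM = 999


def main() -> None:
    beh = io.read_tsv(ROOT / "results/data/behavior.tsv")
    fa = io.read_tsv(ROOT / "results/data/fa_regions.tsv").drop(columns="subject")
    scores = io.read_tsv(ROOT / "results/ica/subject_scores.tsv")
    meta = json.loads((ROOT / "results/ica/decomposition.json").read_text())
    score_mat = scores[[f"ic{c + 1}" for c in range(K)]].to_numpy()
    base_cov = beh[["sex", "age", "hand", "icv"]].astype(float)

    # region table for the component tracking planted network 1, three scopes
    est_for_planted = {p: e for e, p in enumerate(meta["estimated_to_planted"])}
    c = est_for_planted[0]
    cov = base_cov.copy()
    for j in range(K):
        if j != c:
            cov[f"ic{j + 1}"] = score_mat[:, j]
    scoped = []
    for scope, table in hemisphere_scopes(fa).items():
        out = fit_fa_models(score_mat[:, c], table, cov, apply_fdr=False)
        out.insert(0, "scope", scope)
        scoped.append(out)
    regions = pd.concat(scoped, ignore_index=True)
    regions["q"], _ = bh_fdr(regions.p.to_numpy())  # 3 scopes x 35 regions
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_tsv(regions, OUT / f"fa_regions_ic{c + 1}.tsv")
    top = regions.sort_values("p").iloc[0]
    print(f"IC{c + 1} region table ({len(regions)} scope x region tests): "
          f"strongest {top.scope}/{top.region}, beta = {top.beta:+.2f}, q = {top.q:.3g}")

    summary = fa_component_summary(score_mat, fa, base_cov, n_perm=N_PERM, seed=4)
    io.write_tsv(summary, OUT / "fa_component_summary.tsv")
    for _, r in summary.iterrows():
        print(f"  IC{int(r.component) + 1}: KS D = {r.ks_D:.2f} (q = {r.ks_q:.3g}), "
              f"{int(r.n_nominal_significant)}/70 regions nominal, "
              f"p_empirical = {r.empirical_p:.3g} (q = {r.empirical_q:.3g})")


if __name__ == "__main__":
    main()
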