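# wmnet

Spatial ICA decomposition and functional annotation of working-memory fMRI
contrast maps.

Verbal n-back experiments yield one 2-back − 0-back contrast map per subject.
The voxels reliably more active under memory load (the working-memory
network, WMN) span fronto-parietal cortex, but that blanket network mixes
functionally distinct subsystems. `wmnet` implements a pipeline that
separates them: it decomposes the subjects × voxels contrast matrix **X**
into statistically independent spatial sources **S** (z-scaled voxel
loadings) and per-subject mixing coefficients **A** (subject scores),
`X ≈ A·S`, and then asks which networks carry individual differences in task
performance (signal-detection d′ = Φ⁻¹(H) − Φ⁻¹(F)), how stable they are
under resampling, and whether their scores track white-matter microstructure
(region-wise fractional anisotropy, FA).

The package is written for methods work at desk scale: a synthetic-data
generator plants known spatial sources, mixing scores, batch structure,
behavioral slopes and FA effects, so every stage of the pipeline can be
validated against ground truth.

## What is in here

| module | role |
| --- | --- |
| `wmnet.synthetic` | datasets with planted ground truth: sparse Laplace spatial sources, mixing scores, group activation, batch offsets, behavior, FA, atlas, trial-level n-back responder |
| `wmnet.behavior` | n-back schedules (targets, lures), d′ scoring with extreme-proportion correction, exclusion rules, batch residualization |
| `wmnet.groupmask` | missing-data filtering, voxelwise one-sample t, BH-FDR, WMN mask, distribution diagnostics |
| `wmnet.ica` | PCA scree, fixed-point FastICA (log-cosh, symmetric updates), sign recoding, pooled 10% threshold, dual-regression-style score projection |
| `wmnet.annotate` | connected-component clusters, probabilistic-atlas labeling (25% floor, >10-voxel rule), overlap and containment fractions |
| `wmnet.assoc` | standardized multiple regression of scores on performance, collinearity filter, FDR families, voxelwise models |
| `wmnet.stability` | disjoint-split bootstrap with component matching; projection cross-validation with permutation nulls |
| `wmnet.fa` | region-wise FA regressions, KS uniformity test, permutation count test |

The `analysis/` directory holds the numbered drivers that run the whole
study on one synthetic dataset (`01_simulate.py` … `08_fa_associations.py`),
writing tables and volumes under `results/`.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/03_build_mask.py
python analysis/04_decompose.py
python analysis/06_associate.py
```

prints (300 subjects, 16³ grid, four planted networks, noise SD 0.5):

```
WMN mask: 2549 of 4096 voxels (df=299, alpha=0.05)
per-subject skewness range: 0.80 to 3.59; kurtosis up to 35.32
scree: first 6 eigenvalues [25.  21.5 21.3 18.2  1.5  1.5]; cumulative variance at k=4: 29%
FastICA: k=4, converged=True in 8 iterations
matched |r| vs planted sources: [0.795 0.808 0.8   0.812]
pooled 10% threshold: |z| > 1.26 (10.0% of loadings retained)
  IC2 ~ d_prime_2back: beta = +0.21, q = 0.0046, R^2 = 4.3%
  IC4 ~ d_prime_0back: beta = +0.24, q = 0.00049, R^2 = 6.1%
```

Reading this: the group t-map recovers the task-active region as the WMN;
the scree elbow sits at the planted model order (four eigenvalues ≫ 1); the
four recovered loading maps each correlate ≈ 0.8 with their planted sources
after batch residualization; and the standardized regressions recover the
planted behavior couplings — one network carries the 2-back (working-memory)
slope, a different one the 0-back (attention) slope, each with a few percent
of variance explained (R² = t²/(t²+df)). `05_annotate.py` labels the
supra-threshold clusters against the probabilistic atlas, `07_stability.py`
shows split-half loading correlations ≈ 0.9 and cross-validated projections
significant in 48–80% of runs against a ~5% permutation null, and
`08_fa_associations.py` runs the FA arm.

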