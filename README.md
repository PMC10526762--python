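# repsurv

Radiomics and multi-resolution fractal texture analysis of labeled 3D
tumor MRI, balanced-resampling ensemble classification of **rapid early
progression (REP)**, and **copula-based survival analysis under dependent
censoring** — as a tested, reusable Python pipeline.

REP is tumor regrowth between the early post-operative MRI and the
radiation-planning MRI of high-grade glioma patients, and is a negative
prognostic factor. The pipeline this package implements takes
radiation-planning T1 post-contrast volumes with co-registered label
masks (BraTS convention: 1 = necrosis, 2 = edema, 4 = enhancing tumor)
plus a clinical table, and supports three analyses:

1. **Feature extraction** — per tumor region: gray-tone co-occurrence
   (GTSDM), neighborhood gray-tone difference (NGTDM) and gray-level
   size-zone (GLZSM) texture statistics, computed on the raw intensities
   and on three voxel-wise fractal transforms (PTPSA fractal-dimension
   maps, mBm and GmBm Hölder-exponent maps), plus histogram, shape and
   volumetric features (~550 named features per subject).
2. **REP classification** — two-step feature selection (resampled
   univariate screen, then full-cohort significance) and a
   gradient-boosted tree ensemble evaluated over many iterations of
   class-balanced subsampling with stratified k-fold CV, reporting full
   AUC / accuracy / PPV / FPR distributions.
3. **Survival under dependent censoring** — the death time T and
   censoring time U are joined by a Clayton copula with dependence
   `alpha` (Kendall tau = alpha/(alpha+2)). Univariate Cox margins for
   both T and U are estimated semiparametrically by joint maximum
   likelihood; the prognostic index PI = beta(alpha)'x splits subjects
   at the median into good/bad groups; marginal curves come from the
   copula-graphic estimator (exactly Kaplan-Meier at alpha = 0); the
   average vertical distance D between group curves is tested by
   permutation.

Because no patient cohort is distributable, the `synthetic` module is a
first-class component: spectrally synthesized fractional-Brownian
texture with exact Hurst control, nested ellipsoidal tumor phantoms, and
Clayton-coupled Cox-Weibull survival simulations with retained latent
truth, so every estimator is testable against known ground truth.

## Worked example

Simulate a cohort with strong dependent censoring (alpha = 8, Kendall
tau = 0.8), fit dependent-censoring Cox models, form prognostic groups
and test their separation:

```python
import numpy as np
from repsurv import (ClaytonCopula, CopulaSurvivalTruth, gen_copula_survival,
                     fit_dependent_cox, cg_estimator, split_by_pi,
                     prognostic_index, permutation_test, vertical_distance)
from repsurv.survival import standardize

truth = CopulaSurvivalTruth(alpha=8.0, beta=(0.7, -0.5), gamma=(0.4, 0.0),
                            n=300, seed=42)
data = gen_copula_survival(truth)

copula = ClaytonCopula(8.0)
z = standardize(data.x)
fits = {c: fit_dependent_cox(z[c].to_numpy(), data.time, data.event, copula,
                             feature=c) for c in z}
pi = prognostic_index({c: f.beta for c, f in fits.items()}, z)
groups = split_by_pi(pi)
curves = {g: cg_estimator(data.time[groups == g], data.event[groups == g],
                          copula, group=g) for g in ("good", "bad")}
D = vertical_distance(curves["good"], curves["bad"])
res = permutation_test(data.time, data.event, groups, copula,
                       n_perm=1000, seed=0)
```

Output:

```
simulated n=300, censored fraction=0.15, Kendall tau=0.80
x0: beta=+0.564 (se 0.068, p=7.4e-17)
x1: beta=-0.270 (se 0.063, p=1.8e-05)
groups: good=150, bad=150
vertical distance D=0.238, permutation p=0.0010
```

The fitted coefficients recover the simulated effect directions under
the true dependence; the low-PI half of the cohort survives visibly
longer than the high-PI half (D = 0.238), and 1000 group-label
permutations put that distance far outside the null (p = 0.001, the
smallest value the add-one convention allows at 1000 permutations).

A full imaging run works stage by stage from one YAML config:

```bash
repsurv simulate          --config cfg.yaml   # phantom NIfTIs + clinical CSV
repsurv extract-features  --config cfg.yaml   # per-subject feature CSV
repsurv classify-rep      --config cfg.yaml   # metric distributions, selected features
repsurv survival-select   --config cfg.yaml   # alpha, fits, groups, D, p, crosstab
```

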