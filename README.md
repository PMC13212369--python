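# fhoc

Morphometry and growth-chart modeling for the **femoral head ossification
center (FHOC)** — the secondary ossification nucleus of the capital femoral
epiphysis visible on anteroposterior (AP) pelvic radiographs of children.

The package is aimed at researchers building or validating automated
measurement pipelines for pediatric hip radiographs. It covers the three
analysis stages that sit downstream of any detector/segmenter:

1. **Measurement** (`fhoc.measurement`) — given a binary segmentation mask and
   its pixel spacing, detect the two cortical landmarks (medial margin and
   outermost lateral point) and compute the FHOC size as the *maximum
   transverse diameter*: the Euclidean distance between the extreme-column
   boundary points, in mm.
2. **Evaluation & agreement statistics** (`fhoc.seg_metrics`,
   `fhoc.agreement`) — Dice similarity coefficient and exact Hausdorff
   distance for masks; mean radial error (MRE) and successful detection rate
   (SDR at 1/2/2.5/3/4 mm) for landmarks; Lin's concordance correlation
   coefficient (CCC) with Fisher-type CI, Pearson *r*, MAE/RMSE with bootstrap
   CIs, Bland–Altman bias and 95 % limits of agreement (LoA) with a
   proportional-bias check, paired *t*-test, and Fisher's *Z*-test for
   comparing correlations — all available per sex / side / age-bin stratum.
3. **Growth charts** (`fhoc.growthchart`) — monotone polynomial **quantile
   regression**: for each quantile level τ the curve minimizes the pinball
   loss Σᵢ ρ_τ(yᵢ − p(aᵢ)), ρ_τ(u) = u·(τ − 𝟙{u<0}), over polynomial
   coefficients subject to p′(a) ≥ 0 on an age grid, solved exactly as a
   linear program. Fitted quantiles are rearranged (sorted per age) so
   percentile curves never cross. Products: percentile reference tables,
   per-measurement percentile lookup, adjusted R² of the median curve, and
   per-age-bin MAE/RMSE.

Because clinical radiograph cohorts are private, `fhoc.synthetic` generates
the study material: mask images with analytically known landmark/diameter
ground truth, and bilateral measurement cohorts (ages 0.5–11 y, both sexes)
whose per-age size distribution reproduces published 5th/50th/95th percentile
reference values for healthy Korean children, plus simulated reader
re-measurements with configurable bias and noise.

## Worked example

```python
import numpy as np
from fhoc import (GeneratorConfig, gen_cohort, gen_paired_measurements,
                  bland_altman, ccc, fit_quantile_curves, predict_percentiles,
                  percentile_of)

# 600 children (25 per sex per age bin), bilateral -> 1200 hips,
# plus an unbiased simulated reader with 0.96 mm noise
cohort = gen_cohort(GeneratorConfig(n_per_sex_per_agegroup=25, seed=501))
paired = gen_paired_measurements(cohort, bias_mm=0.0, noise_sd_mm=0.96, seed=502)

x, y = paired["size_mm"].to_numpy(), paired["reference_mm"].to_numpy()
print(f"CCC  = {ccc(x, y).value:.3f}")
ba = bland_altman(x, y)
print(f"bias = {ba.bias_mm:+.3f} mm, LoA = [{ba.loa_low_mm:+.2f}, {ba.loa_high_mm:+.2f}] mm")

models = fit_quantile_curves(cohort, degree=3)
print(predict_percentiles(models["female"], ages=[1, 5, 11])
      [["age_years", "q5_mm", "q50_mm", "q95_mm"]].round(1).to_string(index=False))
print(percentile_of(models["female"], age=5.0, size_mm=28.0).display)
```

prints

```
CCC  = 0.996
bias = +0.021 mm, LoA = [-1.82, +1.87] mm
 age_years  q5_mm  q50_mm  q95_mm
       1.0    6.5    10.0    13.8
       5.0   22.2    26.3    29.7
      11.0   37.1    42.3    48.2
73.3
```

The CCC near 1 and the ±1.9 mm limits of agreement say the two "methods"
(here: truth vs a 0.96 mm-noise reader) are interchangeable at the sub-2 mm
level; the percentile table is the growth chart evaluated at three ages, and
the final number places a 28 mm ossification center at the 73rd percentile
for a 5-year-old girl.

A command-line interface mirrors the library:

```bash
fhoc simulate --out run/ --seed 7
fhoc measure --mask mask.png --spacing-mm 0.2 --side left
fhoc agree --cohort run/cohort.csv --by sex
fhoc growthchart fit --cohort run/cohort.csv --out model.json
fhoc run-all --out run/ --seed 7
```

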