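# fociquant

Quantification of endogenous γ-H2AX foci — the punctate immunofluorescent
marks that phosphorylated histone H2AX forms at DNA double-strand breaks —
in two-channel fluorescence micrographs of peripheral-blood mononuclear
cells, together with the cohort statistics used to relate mean foci/cell to
age and to age-related disease.

The package is aimed at people studying DNA-damage biomarkers of aging who
need (a) a reproducible, operator-free per-nucleus focus counter and (b) the
piecewise-regression / subgroup-comparison machinery that goes with it.
Because no raw patient images or per-patient tables are publicly available
for this design, the package also ships first-class synthetic generators —
for micrographs with planted ground truth and for a 40-patient cohort —
so every stage can be validated by parameter recovery.

## What it computes

**Imaging.** Each image is a registered pair: DAPI (nuclei) and Cy3
(γ-H2AX). The pipeline applies a fixed preset enhancement chain
(auto-contrast, auto-levels, desaturate, invert) identically to every image,
segments nuclei from the DAPI channel (Gaussian smoothing, Otsu threshold,
hole filling, 8-connected labeling), excludes deformed or fragmented nuclei
(area and solidity QC plus a border rule — the proxy for apoptotic cells),
detects spots on the Cy3 channel alone with multi-scale
Laplacian-of-Gaussian blob detection, and counts only the foci that fall
inside a QC-passing nucleus. Per-patient output is the mean foci/cell over
all QC-passing cells, with its SEM.

**Statistics.** The age trend of mean foci/cell y is modeled as a hinge
(change-point) regression

    y = β₀ + β₁·age + δ·max(0, age − τ) + ε,

where β₁ is the first-segment slope, β₁ + δ the second, and τ the change
point, estimated by grid search over integer candidate ages (minimum SSE;
ties to the smallest candidate). Standard errors, CIs and p-values are
conditional on the estimated τ being fixed, and the report says so — such
p-values are biased downward. Disease subgroups are compared by OLS with
and without age and sex adjustment, with integer percent change
round(100·(mean_with − mean_without)/mean_without) and optional subset
filters (e.g. `age >= 57`).

## Worked example

```python
import numpy as np
from fociquant import (ImageSimParams, generate_image, quantify_image,
                       CohortSimParams, simulate_cohort, fit_changepoint)

# simulate one field of view and count foci per nucleus
img, truth = generate_image(ImageSimParams(n_nuclei=30, noise_sd=200, seed=0))
records = quantify_image(img)
print(len(records), "QC-passing nuclei,",
      np.mean([r.foci_count for r in records]).round(2), "foci/cell")

# simulate a cohort and fit the change-point model
cohort = simulate_cohort(CohortSimParams(seed=42))
fit = fit_changepoint(cohort["age"].to_numpy(),
                      cohort["mean_foci_per_cell"].to_numpy())
print(f"change point {fit.tau_hat:.0f} y, slopes "
      f"{fit.slope1:+.3f}/{fit.slope2:+.3f}, R2 {fit.r2_linear:.3f} -> "
      f"{fit.r2_changepoint:.3f}")
```

prints

```
25 QC-passing nuclei, 4.12 foci/cell
change point 48 y, slopes +0.301/-0.000, R2 0.243 -> 0.450
```

i.e. 25 of the 30 simulated nuclei passed QC (this seed planted 5 deformed
nuclei, all correctly excluded) with on average 4.12 counted foci each, and
on this single 40-patient draw the grid search put the kink at 48 years
with foci/cell rising ~0.30/year before it and flat after — adding the
hinge lifts R² from 0.243 to 0.450. A single cohort of 40 is deliberately
noisy (the generating kink is 57 and the generating first slope 0.176);
the recovery study below is the calibrated, replicated version of this
experiment.

The numbered scripts under `analysis/` run the full narrative — simulate
micrographs at three cytocentrifugation-stress levels, count foci, simulate
the cohort, fit the change-point model, run the subgroup comparisons — and
write their tables under `results/`.

## Command line

A thin CLI wraps the library:

```
fociquant simulate-images --n-images 4 --lambda 4.25 --stress 0 --seed 0 --outdir imgs/
fociquant count --input-dir imgs/ --per-cell-out cells.csv
fociquant simulate-cohort --seed 42 --out cohort.csv
fociquant changepoint --cohort cohort.csv --out fit.json
fociquant compare --cohort cohort.csv --subset "age>=57" --out table.csv
```
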