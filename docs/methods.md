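# Methods

## The measurement model

A γ-H2AX focus is a diffraction-limited to ~µm-scale bright spot in the Cy3
channel; one focus is taken as one DNA double-strand break site. The unit
of measurement is the *count of foci inside one DAPI-defined nucleus*, and
the per-patient statistic is the arithmetic mean of that count over all
QC-passing cells pooled across a patient's images, with SEM = sd/√n_cells.
Pooling across cells (rather than averaging per-slide means) is a design
choice; with roughly balanced slides the two differ negligibly.

## Synthetic micrographs (`image_model`)

The generator renders what the counting pipeline must be robust to, not
photorealism:

- **Nuclei** are smooth filled ellipses (mean radius 18 px, relative SD
  0.12 truncated at ±2 SD, elongation ≤ 1.25, random orientation), placed
  by rejection sampling with non-overlap plus a 5 px clearance so masks of
  neighboring nuclei stay disjoint after smoothing. Placement failure after
  a bounded number of attempts raises an overcrowding error.
- **Deformed/fragmented nuclei** (fraction `deformed_fraction`) model the
  apoptotic cells a counter must exclude. Half are fragmented into 2–4
  small disjoint pieces (each piece far below the typical nucleus area);
  half are rendered as thick annular arcs ("horseshoes", solidity ≈ 0.7
  after rendering) that pass the area band but fail the solidity cut. Both
  shapes were chosen so the QC filter has a clean, testable signal.
- **Foci** per nucleus are K ~ Poisson(`focus_rate_lambda` +
  `stress_level`), rendered as isotropic Gaussian spots (σ = 1.5 px,
  amplitude 15 000 on a 16-bit range above a flat background of 800).
  The default rate 4.25 foci/cell is the cohort-wide mean this design
  emulates. `stress_level` adds to the rate and stands in for
  cytocentrifugation G-force: only the qualitative monotone dose-response
  is claimed, no quantitative rpm→rate map.
- **Focus placement** is uniform inside the nucleus ellipse except for two
  margins: centers stay ≥ 2σ inside the rim (foci are chromatin-bound and
  wholly intra-nuclear, and a spot centered on the mask edge would be
  ambiguous to any counter), and planted foci keep a minimum mutual
  separation of 3.5σ ≈ 5.25 px. Two Gaussian spots closer than ~3σ merge
  into a single intensity peak, which no resolution-limited counter, human
  or algorithmic, can split — so the simulator plants *discrete,
  individually resolvable* foci. Placement uses hard-core dart throwing
  with restarts (near-uniform), falls back to best-candidate sampling for
  crowded nuclei, and only then relaxes the separation stepwise; a relaxed
  nucleus mirrors a real over-crowded nucleus whose counts saturate.
- **Noise** is i.i.d. Gaussian read noise added to both channels, then
  clipping to the bit range. Everything is reproducible bit-for-bit from
  the integer seed.

Not modeled (deliberately): PSF physics, z-stacks (analysis is 2-D),
chromatic shift, uneven illumination, intensity variation between foci,
autofluorescence texture. Passing tests therefore demonstrate correctness
of the counting logic under controlled conditions, not performance on real
micrographs.

I/O is 2-page TIFF (page 1 DAPI, page 2 Cy3; pixel size in a JSON image
description, default 0.065 µm at 100× scale) with a JSON ground-truth
sidecar; coordinates are 0-based (row, col) with pixel centers at integers.

## The counting pipeline (`focus_quant`)

1. **Preset enhancement** — a fixed, operator-free chain applied
   identically to every image: auto-contrast (linear stretch of the
   luminance quantiles `clip_fraction` … 1−`clip_fraction` to the full bit
   range, one common scale across bands), auto-levels (the same stretch per
   band), desaturate (mid-channel gray 0.5·(max+min); identity on single-
   band input), invert. Clip fractions default to 0.001, the classical
   0.1 % auto-stretch of desktop imaging tools. A constant image has no
   dynamic range and is returned inverted with a warning. The chain ends
   in the inverted polarity used for visual counting (dark spots on light);
   the pipeline re-inverts before spot detection.
2. **Nucleus segmentation** — Gaussian smoothing (σ = 2 px), global Otsu
   threshold, hole filling, 8-connected labeling. QC per nucleus: solidity
   ≥ 0.85, area within [m/3, 3m] where m is the *area-weighted median*
   component area of the image (the plain median is not robust when
   apoptotic fragments outnumber intact nuclei), and no contact with the
   image border. Only QC-passing nuclei are counted.
3. **Spot detection** — scale-normalized Laplacian-of-Gaussian over 5
   log-spaced scales in σ ∈ [1.0, 2.5] px (matched to the simulator's spot
   width; widen for data with larger foci). Candidates are local maxima
   over space and scale above 0.10 × the global response maximum, with a
   numerical floor so separable-filter error on flat regions can never
   trigger; candidates closer than 3 px are merged keeping the stronger.
   Detection runs on the enhanced Cy3 channel alone — counting without the
   DAPI overlay gives better contrast — and replaces the human counter;
   it is validated against simulator ground truth, not human counts.
4. **Enumeration** — each detection is assigned to the QC-passing nucleus
   whose rasterized mask contains its rounded position; detections outside
   every mask are discarded; every QC-passing nucleus yields a record,
   including zero-count ones. Counting is independent of detection order.

On clean synthetic images (no noise, no deformed nuclei, default rate) the
pipeline count equals the planted count for 100 % of nuclei; under read
noise of 200 (≈1/75 of spot amplitude) the per-nucleus MAE stays ≪ 0.5.
No absolute calibration against any real-world foci/cell level is claimed:
absolute counts are known to be strongly methodology-dependent.

## Synthetic cohort (`cohort_sim`)

Forty patients (26 M / 14 F), ages uniform on [35, 83] (an explicit age
vector can be supplied instead). Expected foci/cell:

    μ(age) = b₀ + β₁·age + δ·max(0, age − τ) + Σ_d γ_d·flag_d

with defaults β₁ = 0.176 foci/cell/year, δ = −0.217 (second slope −0.041),
τ = 57 y. The intercept is not recoverable from the published record; the
default b₀ = 4.89 − 0.176·54.5 ≈ −4.70 anchors the model to 4.89 foci/cell
at the midpoint of the 50–59 decade. Recovery targets depend only on the
slopes and τ.

Observation model: latent patient mean = μ + N(0, σ²), clipped at zero
(counts cannot be negative; a warning is issued), then the observed value
is the average of per-cell Poisson counts for 120–400 cells/patient —
Poisson is the minimal assumption for count data, and at these cell numbers
it adds ≤ 0.02 to the patient-level variance. Disease subgroups of fixed
size (hypertension 15/40, vitamin D deficiency 5/40, cataracts 4, sleep
apnea 3, irradiation 2, BPH 7, any cancer 8) receive additive mean shifts
set from the published with/without group differences; comorbidity
correlation is not modeled.

The default residual SD σ = 1.42 anchors the cohort's *total* dispersion to
the published all-patient SEM (0.28·√40 ≈ 1.77 SD) after subtracting the
systematic variance of the hinge model under the uniform age design
(≈ 1.11). `calibrate_sigma(params, target_r2)` instead solves
Var(systematic)/(Var(systematic)+σ²) = target_r2 with Var(systematic) from
a 10⁶-draw Monte Carlo over the age (and disease-flag) distribution; the
recovery study uses `target_r2 = 0.142`, giving σ ≈ 2.59.

## Change-point regression (`changepoint`)

OLS is closed-form (QR solve; covariance σ̂²(XᵀX)⁻¹; two-sided t
p-values), raising a named error on rank-deficient designs. The hinge model
is fitted at every candidate τ on an integer grid (default min(age)+4 …
max(age)−4; candidates must leave ≥ 3 observations strictly on each side);
τ̂ minimizes the SSE, ties to the smallest candidate — "best overall model
fit" operationalized as minimum SSE, equivalently maximum R². The second-
segment slope is β₁+δ with SE from the full linear combination
(var β₁ + var δ + 2 cov). All inference is *conditional on τ̂ fixed*
(t with n−3 df); every report carries the caveat that these SEs ignore the
change point's own uncertainty and the p-values are biased downward. A
nonparametric bootstrap for τ̂ is provided as a clearly-labeled optional
extra outside that conditional convention. The published 95 % CI for the
first slope (0.094–0.258) is not reproducible from its printed SE (0.071)
under any standard t/normal construction; this package reports t-based CIs
and does not force agreement.

### Estimator behaviour under the calibrated design — a known bias

The recovery study (200 cohorts, σ calibrated to R² = 0.142) shows:

- the **change point** is recovered well: the median τ̂ lands within ±2
  years of the generating 57 across seeds;
- the **first-segment slope conditional on the grid-searched τ̂** is *not*
  unbiased at this noise level. Selecting τ by minimum SSE favors
  replicates/configurations with steeper first segments (≈ +0.08 on the
  mean under Gaussian noise), partly offset (≈ −0.05) by the zero-clipping
  of latent means at young ages; the net replicate mean sits near 0.20
  rather than 0.176, with a Monte-Carlo SE of ≈ 0.016 at 200 replicates.
  Conditioning on the *true* τ removes the effect entirely (bias < 0.02,
  verified in the test suite). This is a property of grid-search
  change-point estimation in weak-signal regimes, not an implementation
  artifact — the oracle tests show exact agreement with an independent
  exhaustive search.

For the same reason the realized R² of the fitted change-point model is
inflated relative to the population target (selection over ~40 candidates
plus small-sample optimism ≈ (1−R²)·2/(n−1)); the calibration is defined on
the population decomposition, which is the reproducible quantity.

`decade_summary` bins patients by calendar decade and reports mean ± SEM
per bin (SEM missing for singleton bins). Note that under a *uniform* age
fill the model's decade means peak in the 60s, not the 50s: the published
decade ordering reflects that cohort's specific age composition.

## Subgroup comparisons (`group_comparison`)

Means ± SEM across patient means per group; integer percent change
rounded half-away-from-zero (the convention that reproduces every
self-consistent published triple); p-values from the group coefficient in
OLS y ~ group (unadjusted — equivalent to the two-sample t test) and
y ~ group + age + sex (adjusted). Subset filters are pandas query strings
(e.g. `"age >= 57"`). With a perfectly balanced design the adjusted and
unadjusted group-effect *estimates* coincide exactly; the p-values differ
slightly through the residual degrees of freedom. No multiple-testing
correction is applied across the disease panel, mirroring the original
analysis; all raw p-values are surfaced so users can correct as they see
fit. `top_k_flag_enrichment` sorts by foci/cell (ties by patient id) and
reports how many of the top k carry a flag.

## Problem sizes and numerics

Default test/validation sizes: 210 nuclei for exact-count validation,
≥ 500 for noisy-MAE, ≥ 1000 planted nuclei per stress level for
monotonicity, 10 000 for the Poisson-rate check, 200 replicates for the
recovery study, 10⁶ draws for σ calibration — sizes chosen so that binomial
/ CLT bands in the tests are decisive. SSE ties in the grid search use a
1e-12 absolute guard; detection uses a relative threshold with an absolute
numerical floor; intensity rasters are finite-checked at entry. All
randomness flows from integer seeds through `numpy.random.default_rng`.
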