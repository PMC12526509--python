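# Methods

`smctex` estimates volumetric soil moisture content (SMC) in three depth
layers (0–20, 20–40, 40–60 cm) from six-band canopy reflectance imagery
(blue 450, green 555, red 660, red-edge 720, red-edge 750, NIR 840 nm).
The chain is: vegetation masking → windowed GLCM texture extraction →
2-D/3-D texture-index construction → exhaustive correlation screening per
depth → regression modeling (RF, PLSR, BPNN) over seven input
combinations. Because no field data are distributed with the package, a
synthetic canopy generator supplies imagery with a known, controllable
texture–moisture coupling; it is first-class, tested code.

## Vegetation masking

Pixels are retained where NDVI = (NIR − Red)/(NIR + Red) exceeds a
threshold τ, then the binary mask is refined by 3×3 morphological opening
followed by closing (standard border convention: erosion treats the
outside as vegetation, dilation as background, which keeps opening
anti-extensive, closing extensive, and the composite filter idempotent).
τ can be fixed or selected automatically as the Otsu
(minimum-intra-class-variance) threshold of the index histogram, clamped
to [0.30, 0.40] — the conventional NDVI masking range. The Otsu objective
is computed in float64 over 256 candidate cuts; when two well-separated
modes leave an empty gap, every cut inside the gap ties exactly, and the
plateau midpoint is returned so the threshold falls between the modes
rather than at an arbitrary plateau edge. An NDRE variant is available
(`index_name="ndre"`); the masking index is configurable because the
0.30–0.40 range is an NDVI convention, not a law.

## GLCM texture features

Eight second-order statistics per band — MEA, VAR, HOM, CON, DIS, ENT,
SEC, COR — yield 48 "positions" (metric × band, e.g. HOM6 = homogeneity
of the NIR band). Fixed protocol: 64 gray levels, 5×5 moving window,
one-pixel offset, four directions (0°, 45°, 90°, 135°) accumulated
symmetrically and averaged.

Numerical and convention choices:

* **Quantization** scales each band linearly to levels 0..63 between the
  1st and 99th percentiles of the masked pixels (per plot); percentile
  clipping guards against hot pixels. A `scaling_mode="global"` option
  accepts fixed per-band ranges for cross-flight comparability. Levels
  are 0-based; this shifts MEA by a constant relative to a 1-based
  convention and is irrelevant to every correlation downstream.
* **Entropy** uses the Shannon form −Σ P log P in natural log, so
  ENT ≥ 0 (recorded in `TEXTURE_METADATA`). A printed GLCM entropy
  without the minus sign is nonpositive and contradicts the universal
  definition.
* **Correlation** uses the marginal means/variances of the symmetric
  matrix (MEA_i = MEA_j under symmetry), the standard GLCM correlation.
  Windows whose matrix has zero variance contribute "undefined" to COR
  and are excluded from COR's plot mean only.
* **Windows** are interior-only (no padding); a window is admissible when
  ≥ 60% of its pixels are vegetation (`min_window_valid_frac = 0.6`). A
  direction with zero valid pixel pairs in a window is skipped; the plot
  value is the arithmetic mean of the per-window direction-averages (the
  aggregation convention for plot-scale GLCM statistics).
* The vectorised sliding-window implementation shifts levels by the plot
  mean before forming moment sums (differences and covariances are
  shift-invariant) to keep the E[x²] − u² cancellation benign; it agrees
  with an explicit triple-loop reference to ~1e−15 relative.

## Texture indices

Six two-position families (ATI, DTI, NDTI, RTI, RDTI, RATI) and four
three-position families (BDSI, DTTI, MSI, NDTTI) combine position values
arithmetically (e.g. DTTI = T_i − T_j − T_k). Tuples are ordered and
repetition is allowed, so each 2-D family spans 48² = 2 304 and each 3-D
family 48³ = 110 592 combinations. Degenerate denominators yield NaN (an
undefined marker) rather than an epsilon-stabilised value — epsilon
choices would silently distort the correlation ranking the screening
depends on. A combination with more than 10% undefined rows is dropped.

## Correlation-matrix screening

Per depth and family, the Pearson correlation of every combination with
SMC is evaluated (vectorised, blockwise over the leading index to bound
memory); p-values come from the t-transform t = r√((n−2)/(1−r²)) with
n−2 df. The maximum-|r| combination is reported, with exact ties broken
lexicographically by combination name. Two caveats on ties: MSI is
permutation-invariant and BDSI obeys BDSI(i,j,k) = 1 − BDSI(i,k,j), so
those families contain combinations whose |r| ties by algebraic identity;
evaluation-order rounding (~1 ulp) then decides which member the argmax
reports.

Filters, in order: significance (raw p < 0.05, no multiplicity
adjustment; a Bonferroni flag exists but defaults off), greedy redundancy
removal (walk features by descending |r| with SMC, keep only those with
|r| < 0.90 against everything already kept), and iterative VIF pruning
(drop the largest VIF until all VIF_j = 1/(1−R_j²) ≤ 10). For index
families the filters apply to the best combination plus any within 95% of
the best |r| (capped at 20 per family, configurable) — the exhaustive
grids exist to find maxima, not to feed 110 k columns to a model.

## Models and evaluation

Plots are split 2:1 into training and validation by SMC-stratified
sampling (sort by SMC, strata of three, one random plot per stratum to
validation). Predictors are z-standardized with training statistics
(population sd); the same parameters apply to held-out rows. Within
training, a single 10-fold plan is shared by all model families.

* **RF**: 200 trees, squared-error split criterion (the variance-reduction
  criterion appropriate to regression), all features per split, OOB score
  recorded.
* **PLSR**: components added while each addition raises the 10-fold
  CV-predicted cumulative explained variance of Y by ≥ 5 points
  (CV-predicted, not calibration, variance — the honest generalisation
  estimate).
* **BPNN**: one hidden tanh layer trained by lbfgs (quasi-Newton, batch).
  Hidden size is selected over {10, 15, …, 100} by fold-averaged CV RMSE
  at a fixed moderate weight decay; the L2 weight decay is then selected
  on the same folds over {10⁻³, 10⁻², 10⁻¹, 1, 10}; finally ≥5 restarts
  are scored by the same CV RMSE and the best initialisation is refit on
  the whole training set. Validation-selected weight decay is the
  capacity control here, playing the role early stopping plays in
  Levenberg–Marquardt training; with a fully converged batch optimizer
  and n ≈ 64, an unregularised network memorises the training set.

Metrics on the held-out validation set: R² = 1 − SSE/SST, RMSE in SMC
percentage points, MRE = mean(|ŷ−y|/y)·100%. SMC is carried internally
as a volumetric fraction and converted to percent for modeling and
reporting. Seven input combinations — the non-empty subsets of {raw
textures, 2-D indices, 3-D indices} — are crossed with the three model
families and three depths (63 cells); a failed cell is flagged, never
fatal.

**Leakage**: the default (`strict`) mode screens features on training
rows only. A `screen-first` mode screens on all plots before splitting,
reproducing the order used in field studies that report screening tables
on the full sample; its validation scores are optimistically biased and
the mode exists for comparability, not inference.

## Synthetic data generator

Each plot's canopy is a Gaussian random field: white noise shaped in the
Fourier domain by a power-law spectrum k^(−β/2), standardized, scaled by
per-band gains (red-edge/NIR strongest: gains 0.7–1.0 vs 0.2–0.3 for
VIS) around typical wheat-canopy reflectances, plus i.i.d. sensor noise
(sd 0.01 reflectance). Shallow SMC s (normalized to its range) drives
β = 1.2 + 2.6·κ₁·s and the field amplitude 0.04·(1 − 0.6·κ₁·s): wetter
plots are smoother and more homogeneous, so windowed contrast falls
monotonically with SMC — the generator's defining, tested contract.
Bernoulli soil seeds (p = 0.015) dilated 3×3 carve low-NDVI gaps
(soil spectrum, NIR ≈ red), covering ≲15% of pixels, so the masking
stage has real work.

Depth structure is AR(1) across layers with ρ = 0.75 on a latent normal
scale, mapped into the SMC range (0.08–0.30 m³ m⁻³, mid ± 3 sd spanning
the range, clipped at the bounds). Imagery depends only on shallow SMC,
so the texture–SMC correlation of layer d decays as ρ^(d−1): the nominal
per-layer couplings κ = (0.90, 0.68, 0.51) equal κ₁·ρ^(d−1) and are
validated as non-increasing. ρ = 0.75 keeps a meaningful but clearly
weaker signal in the mid/deep layers, mirroring how canopy-derived
features track near-surface moisture best while deeper layers correlate
only through the moisture profile's vertical coherence.

Defaults: 96 plots of 64×64 px, three layers — the trial size the
analysis is designed around. What the generator does **not** emulate:
radiative transfer, irrigation/fertilization treatment structure, row
geometry, shadows, view-angle effects, or any calibrated SMC→reflectance
physics. Passing recovery tests therefore shows the pipeline recovers a
known monotone texture–moisture coupling and its depth ordering — not
that the specific correlation magnitudes transfer to real fields.

## Problem sizes used in tests and reproduction runs

Unit and pipeline tests use 24 plots of 32×32 px; the recovery tests and
the reproduction script use the full default trial (96 plots, 64×64 px)
across five seeds (tests) or one seed (script). The reproduction script
runs RF/PLSR over all seven combinations and BPNN over the baseline and
fusion inputs, the cells its reported quantities need.

## Known limitations

* The synthetic coupling form is a stand-in; no quantitative SMC→texture
  model exists to calibrate it against.
* Mid/deep-layer scores are bounded by ρ² and ρ⁴ of the shallow signal by
  construction; they are structurally, not physically, meaningful.
* BPNN results depend on the weight-decay grid; the grid is coarse by
  design (capacity control, not fine tuning).
* `run_grid` assumes one image per plot per campaign; multi-temporal
  stacks are out of scope.
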