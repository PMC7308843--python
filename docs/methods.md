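# Methods

This note documents the models and procedures implemented in `berryspec`,
the synthetic data they are validated against, and the design decisions
taken where the methodology was genuinely open.

## The analysis problem

Each sample is one strawberry imaged by a visible/NIR hyperspectral camera
(374–1020 nm, 2.31 nm steps, 280 bands), with destructive reference values
of soluble solid content (SSC, %), pH, and vitamin C (VC, g·kg⁻¹; from a
juice assay, VC = C·V/M·1000 with C the juice concentration in g·mL⁻¹, V
the juice volume in mL, M the fruit mass in g). The goal is a calibration
model mapping image features to each quality parameter, plus pixel-wise
quality maps.

## Pipeline stages

**Reflectance calibration.** `R = (R_raw − R_dark)/(R_white − R_dark)`
element-wise. A zero `R_white − R_dark` anywhere in the evaluated region is
an error naming the offending element, never a silent NaN.

**Segmentation.** Red fruit against a neutral background separates cleanly
on the super-red score `2R − G − B` built from the band images nearest
691/531/457 nm (nearest-band resolution; ties go to the lower band). The
threshold defaults to Otsu on the score image — the source methodology
names the super-red characteristic but no threshold, so this is a declared
choice, as is the 4-connected largest-component filter that drops bright
background specks. The per-sample spectrum is the arithmetic mean over ROI
pixels, cropped to the closed interval [400, 1000] nm. On the 374 + 2.31k
grid this keeps 259 bands (indices 12–270).

**Color moments (9).** For each of the three channel images restricted to
the ROI: mean, population SD, and the signed cube root of the third central
moment. Reflectance is used directly (no 8-bit quantisation).

**GLGCM texture (15 per band).** Gray level–gradient co-occurrence: the
image crop at the mask's bounding box (background filled with the nearest
ROI pixel so the fruit boundary creates no artificial gradients) is paired
with its 3×3 Sobel gradient magnitude; both are quantised to 16 levels by
max-scaling `x → round(x·(L−1)/max)` (all-zero when max ≤ 0); the joint
histogram over ROI pixels is normalised to p(i,j). The 15 statistics —
small/big grads dominance, gray/grads asymmetry (marginal energies),
energy, gray/grads mean, gray/grads variance, correlation, gray/grads/joint
entropy, inertia, homogeneity — are pinned in `features.py`'s module
docstring as the package's contract, since the cited feature set circulates
without a canonical formula list. Degenerate cases are defined, not NaN:
0·log 0 = 0, correlation = 0 when either marginal SD is 0.

**Gabor texture (3 per band).** Complex Gabor kernel with envelope σx=2,
σy=4 px at 60°; the stated "scale" is read as the envelope SDs, and the
unstated spatial frequency is fixed at 0.25 cycles·px⁻¹ (one cycle per
4 px, resolvable by the σx=2 envelope). The kernel is mean-subtracted to
zero DC gain so flat regions produce no response. Over ROI pixels of the
response magnitude: mean, population SD ("contrast"), and Shannon entropy
of the 64-bin magnitude histogram.

**Pretreatment.** Wavelet denoising: per-spectrum db4 decomposition at
level 3 with symmetric padding, soft thresholding of detail coefficients at
the universal threshold σ̂·√(2 ln n), σ̂ = median|finest details|/0.6745.
MSC: least-squares fit of each spectrum against a reference (x ≈ a + b·m),
returning (x − a)/b. The reference is the column mean of the *calibration*
rows and is frozen for prediction rows; for this reason the split is
computed before pretreatment (on raw cropped spectra), which also keeps the
split itself leakage-free.

**Kennard–Stone split.** Within each storage-time group, ⌈3/4·group⌉
calibration rows by max-min Euclidean selection on column-z-scored
features (the metric space is a declared choice); 5 groups of 24 give
exactly 90/18×5 calibration and 30 prediction samples. Ties break toward
the lower sample id, which makes the split permutation-equivariant.

**Models.** PLSR (mean-centered, component count by 5-fold RMSECV over
1..15 unless fixed); RBF ε-SVR on column-standardised X and standardised y,
hyperparameters from a small seeded cross-validated grid (C ∈ {1, 10, 100},
ε ∈ {0.01, 0.1}, γ = "scale") unless fixed; LWR — per query, the
n_neighbors (default min(30, n)) nearest calibration rows in a PCA space
retaining 99% of calibration variance, Gaussian distance weights with an
adaptive bandwidth (the farthest retained neighbour), weighted linear fit
via least squares with a ridge fallback for singular local systems.
Metrics: R² = 1 − SS_res/SS_tot against each set's own mean; RMSE;
RMSECV pools out-of-fold predictions from seeded shuffled contiguous folds.

**CARS.** Per Monte-Carlo run i (50 runs): fit PLSR on a random 80% of the
calibration rows using currently retained variables; weight each variable
by normalised |coefficient|; force-retain the top ⌈r_i·p⌉ with
r_i = a·e^(−k·i) decaying from 1 (all p variables) to 2/p (two variables);
then survival-resample 5·p draws with replacement proportional to weight
and keep the distinct survivors; score each run's retained set by 5-fold
RMSECV (folds fixed before the loop) and return the subset minimising it.
Two deliberate choices differ from common descriptions:

* *Component count:* fixed at min(15, data caps) rather than chosen by
  inner CV. Before selection the full matrix is noise-dominated and its
  RMSECV-vs-components curve is flat, so an argmin over it is arbitrary —
  in simulation it regularly landed on 1–2 components and degraded the
  coefficient ranking badly.
* *Survival draw count:* 5·p rather than p. With p draws a genuinely
  informative variable holding ~8% of the weight is missed with
  non-negligible probability, and an eliminated variable can never return;
  at 5·p, sampling eliminates only variables whose weight is far below
  1/(5p) and the exponential schedule alone drives the shrinkage.

A caveat users should know: the returned "best RMSECV" is the minimum over
~50 adaptively chosen subsets and is optimistically biased — on pure-noise
targets it sits at roughly 0.5–0.85·sd(y) even though held-out predictive
skill is zero. Judge models by held-out RMSEP, not by the CARS trace.

**UVE.** Append p artificial uniform-noise columns at amplitude
1e-10 × mean column SD, collect PLSR coefficients over leave-one-out
resampling, compute per-variable stability c = mean(b)/sd(b), and keep real
variables with |c| above the 0.99 quantile of |c| over the noise block.
Zero-SD coefficients count as perfectly stable. An empty selection is
returned as such; the pipeline then falls back to the full variable set
with a warning.

**Distribution maps.** A PLSR model trained on the raw ROI-mean spectra at
the top-30 CARS-ranked wavelengths (within the 27–59 range such selections
typically retain) is applied to every fruit pixel's reflectance at those
bands; outside the mask the map is undefined (alpha 0 in the rendered
PNG). Per-pixel pretreatment hooks exist, but per-pixel MSC is *not* used:
regressing a single pixel's spectrum on the calibration reference absorbs
the quality signal itself into the fitted scatter slope and was measured
to collapse the map/truth correlation from ~0.93 to ~0.2–0.3.

## The synthetic data, and what passing tests show

`berryspec.synthetic` emulates the study conditions: 120 fruit in 5
storage-time groups of 24, each a 64×64×280 scene (a desk-scale stand-in
for 692×692 frames) with an elliptical fruit covering ~30% of the frame.

*Forward model.* Reflectance is linear in the [−1, 1]-normalised latents:
a logistic baseline (≈0.12 below 500 nm rising to ≈0.62 on the NIR
plateau) minus compactly supported absorption bumps at 680, 750 and 960 nm,
plus a broad 750–960 nm plateau term. SSC deepens the 680 nm (chlorophyll)
dip and raises the plateau; pH deepens 750 nm and lowers the plateau; VC
deepens 960 nm and lowers the plateau. Compact support (not Gaussians)
makes "unlinked bands are unaffected" an exact, testable statement. Effect
sizes keep reflectance strictly inside (0, 1) over the full latent ranges.

*Latents.* Group means drift with storage — SSC rises then falls
(carbohydrate hydrolysis vs respiration), pH declines 3.22→2.87, VC
declines 0.78→0.54 — with per-fruit normal spread (SD 0.55 / 0.05 / 0.035)
clipped to the observed ranges SSC ∈ [3.4, 8.4], pH ∈ [2.68, 3.33],
VC ∈ [0.4745, 0.8421]. Within each fruit, small linear gradients
(±0.5% SSC, ±0.02 pH, ±0.01 VC across the fruit axis) give the truth maps
spatial structure for map validation; they are zero-mean over the
symmetric mask, so sample-level truth is preserved.

*Distortions.* Per-ROI-pixel multiplicative scatter a + b·R with
a ~ N(0, 0.02), b ~ N(1, 0.05) — exactly the distortion MSC removes —
plus additive camera noise (SD 15 counts against a ~3900-count dynamic
range) inside the mask. White frames carry smooth spatial falloff and an
illuminant spectrum; dark frames a small band-dependent offset. The
background is spectrally flat at reflectance 0.2, so the super-red score
separates fruit (~0.6) from background (0) cleanly.

*What this does not emulate.* No reference-assay noise on SSC/pH/VC, no
chemistry beyond the three absorbers, no photon-noise statistics,
bidirectional reflectance, specular highlights, 3-D geometry, or
achene/calyx structure. Consequently the regression problem is nearly
noiseless at the sample level and prediction R² values of ~1.0 say only
that the pipeline is *correct and lossless*, not that real fruit would be
predicted this well; with real data, expect the relative ordering of
methods to matter more than these absolute scores. Conversely, the exact
inverse-problem checks (calibration ≤ 1e-10, MSC ≤ 1e-10 residual) and
brute-force oracle equivalences (GLGCM joint-table enumeration; LWR and
PLSR against OLS in their limiting regimes) are strong correctness
evidence independent of realism.

## Numerical and degenerate-input conventions

Nearest-band lookup breaks ties toward the lower band. Band cropping is
closed-interval. Zero-variance columns are excluded from z-scored metrics
by setting SD to 1. Constant images yield defined texture values (energy 1,
entropies 0). Constant targets make R² an explicit error, not ±inf. LWR
local fits use `lstsq` (min-norm on rank deficiency) with a logged ridge
fallback for non-finite solutions. All stochastic procedures (scene
generation, Monte-Carlo sampling, fold assignment, grid search) take
explicit integer seeds and are bit-reproducible; reports and artifacts
serialise with sorted keys so identical runs are byte-identical.

## Problem sizes used in validation

The shipped tests and the acceptance script run the full 120-sample
pipeline at the 64×64×280 scene scale, 50-seed selection suites at
n = 90 × p = 200 (recovery) and n = 50 × p = 50 (noiseless support), and
27-cell experiment matrices (3 targets × 3 models × 3 pretreatments);
these sizes exercise every code path while keeping a complete run in the
low minutes on a single CPU.

## Known limitations

* The GLGCM formula set follows one widely used 15-statistic convention;
  other conventions (e.g. SD instead of variance, different dominance
  normalisations) exist and would change absolute feature values.
* The Gabor frequency is a declared constant; the source methodology
  prints only scale and orientation.
* CARS results depend on the Monte-Carlo seed; the best-subset RMSECV is
  optimistically biased (see above).
* UVE's leave-one-out coefficient ensemble costs n PLS fits and is the
  slowest selector path for large n.
* The synthetic generator's linearity means PLSR is the correctly
  specified model; SVR/LWR comparisons on synthetic data should not be
  read as evidence about their relative merit on real fruit.
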