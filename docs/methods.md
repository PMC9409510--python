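# Methods

## Phantom and noise model

The synthetic study emulates replicate PET acquisitions of a NEMA-IQ-style
phantom with three tumor inserts per filling. The inserts are parametric:

* *homogeneous* — an ellipsoid (default semi-axes 16 × 14 × 12 mm, ≈ 11 cm³)
  filled at the tumor activity;
* *necrotic core* — a larger ellipsoid with an inner zero-activity core;
* *half filled* — two overlapping ellipsoidal lobes, one at tumor activity,
  one at background activity.

VOI masks cover the full insert extent including cold regions, as a CT-based
delineation would. Every default insert exceeds 10 cm³, the usual lower bound
for meaningful radiomic analysis; real printed tumor inserts have irregular
meshes that these parametric shapes only stand in for. Fillings use tumor
activities of 14.43, 7.17 and 3.65 kBq/ml over backgrounds of 1.6, 1.61 and
1.22 kBq/ml (nominal TBR 10:1, 5:1 and 2.5:1; the realised ratios are 9.0,
4.5 and 3.0). Activity maps are converted to SUV-like units by dividing by
the background activity, so the background is exactly 1 before noise.

A reconstructed frame is `smooth(truth + ε)`, where ε is a white Gaussian
field with voxel SD

σ(t) = `noise_scale_sigma_ref` · √(t_ref / t),  t_ref = 2400 s,

and the smoothing kernel is the protocol PSF (Gaussian, FWHM 6.5 mm for
EARL1, 5.0 mm for EARL2). Truth and noise are smoothed together; frames of
both protocols generated from the same seed share the pre-smoothing noise
field, so protocol comparisons isolate the PSF. The default
`noise_scale_sigma_ref = 0.12` SUV yields a post-smoothing background COV of
roughly 40% at 5 s (comparable to very low count-statistics imaging such as
⁸⁹Zr-immuno-PET) and about 8% at 120 s (clinical FDG-like); the 2400 s
reference frame carries ≈ 2% background COV and serves as the near-noise-free
ground truth. Seeding: a master seed plus the (filling, duration, replicate)
triple feed a `SeedSequence`, making every frame — and everything downstream —
reproducible and independent of generation order.

What the generator deliberately does **not** emulate: OSEM/TOF/PSF
reconstruction (noise texture and nonnegativity constraints), activity-
dependent noise variance (real PET noise grows with local activity; here the
pre-smoothing variance is spatially uniform), scatter/randoms, CT-based
attenuation effects, and printed-insert mesh geometry. Consequently a passing
study demonstrates that the *method* behaves correctly under controlled
noise–bias coupling, not that specific clinical features are correctable.

The default grid is 96 × 96 × 64 voxels at the scanner voxel size
(3.1819 × 3.1819 × 2.0 mm); the full 256 × 256 × 111 matrix is available via
configuration. The smaller field of view holds the three inserts with ample
background margin and keeps a full two-protocol study (246 simulated volumes,
738 feature extractions) within a desktop-scale run of ~8 minutes.

## Preprocessing and feature set

Image and VOI are cropped to the VOI bounding box plus an 8 mm margin (enough
context for 1 cm³ spherical peak neighborhoods), resampled to 2 mm isotropic
voxels with tri-linear interpolation (voxel-0 centers aligned; the binary
mask is interpolated as a real field and re-binarised at 0.5 fractional
occupancy), and discretised with a fixed bin width of 0.25 SUV anchored at
0 SUV — half-open bins [0, 0.25), [0.25, 0.5), …, with levels clamped at 1 so
slightly negative noise excursions fall in the first bin. The origin and the
0.5 mask threshold are package choices; only the bin width and the 2 mm
tri-linear resampling are prescribed by the workflow being emulated.

The active catalog holds 455 features across ten families. Family sizes:
local intensity 2, statistics 18, intensity histogram 24, intensity-volume
histogram 6, GLCM 25 × 6 aggregations, GLRLM 16 × 6, GLSZM and GLDZM 16 × 3,
NGTDM 5 × 3, NGLDM 17 × 3, minus the three NGLDM dependence-count-percentage
variants, which equal 1 identically when every ROI voxel contributes a
dependence count and are therefore excluded by default. The intensity
histogram family comprises the 23 standard descriptors plus the grey-level
count (the number of occupied discretisation levels), a deliberately simple
24th histogram descriptor that completes the family.

Texture conventions: Chebyshev-distance-1 neighborhoods (26-connected in 3D,
8-connected within axial slices); co-occurrence matrices symmetric;
run-length matrices per direction; zones 26-connected (8 in 2D); GLDZM
distances are city-block distances to the ROI border (border voxels have
distance 1, the image edge counts as border); NGLDM uses grey-level
difference tolerance 0 and dependence count j = 1 + (number of equal-level
neighbors), counting the center voxel. Aggregations follow the usual scheme:
directed families offer per-slice/per-direction averaging, per-slice
direction merging, per-direction slice merging, full in-plane merging, and
3D averaged/merged variants; undirected families offer 2D (slice-averaged),
2.5D (slice-merged) and 3D. Merged variants scale voxel-count normalisers by
the number of merged directions so merged and averaged variants stay
comparable.

Undefined values (skewness of a constant ROI, GLCM correlation of a
single-level ROI, NGTDM coarseness with zero deviation sum, …) are emitted as
NaN; any feature undefined at a duration is excluded from that duration's
ICC/SDM scoring rather than imputed.

## Precision, accuracy, correctability

ICC is the single-measurement absolute-agreement two-way form computed from
ANOVA mean squares with n = 9 tumors as subjects and the k = 10 replicate
frames as raters. SDM uses the sample variance (ddof = 1) of the nine
reference values by default; the population-variance variant is available via
`sdm_ddof=0`. Both statistics are banded at 0.5 / 0.75 / 0.9 with boundaries
going to the higher band.

Classification and gates operate at the noisiest duration (5 s), where
correction matters most; this is configurable. Per-tumor feature summaries
for the rank and trend gates use the median over the 10 replicates. Gate
details: SDM monotonicity demands Spearman r = 1 (ties fail); the trend gate
accepts r ≥ 0.7 for *all* tumors or r ≤ −0.7 for *all* tumors (a mixed set of
directions is uncorrectable in practice since it would need a per-tumor
correction); the COV gate is applied per tumor, all nine required below 30%.

## Correction

Noise estimates come from the difference of replicates 1 and 2 (a single
fixed pair, not an average over pairs): SD_diff is the sample SD of the
difference voxels inside the VOI on the native acquisition grid, COV_diff
divides by the VOI mean of the replicate average. Observations pool all
9 tumors × 4 durations (36 points per feature and mode). Weights are inverse
replicate variances of the regression target (the feature value for the
additive mode, the per-replicate ratio for the multiplicative mode), with the
SD floored at its 5th percentile across the 36 observations to avoid infinite
weights.

The model zoo holds 15 forms: three linear (slope-only, intercept-only with
unit slope, full), two exponentials, a sum of two exponentials, a reciprocal,
two double-exponentials (a Gompertz and exp((a/b)(1 − e^{bx})); an
alternative exp(ab(1 − e^{bx})) parameterisation of the latter is available
via `alt_double_exp2` because the form is genuinely ambiguous), two
logistics, two power laws (a(1 − bˣ) and a·xᵇ), and two rationals. Linear
forms are solved by weighted least squares (statsmodels) or in closed form;
nonlinear forms by `scipy.optimize.curve_fit` — Levenberg–Marquardt when
unbounded, trust-region-reflective where bounds are needed to keep the form
finite on x ≥ 0 (e.g. b > 0 in a·x/(b + x), c ≥ 0 in (a + bx)/(1 + cx),
b ≥ 0 in a·xᵇ). Initial values are data-driven (amplitude from the endpoint
values, rates from log-linearised endpoints); up to 5 jittered restarts are
attempted when a fit fails, after which the model is excluded from selection.

Model selection minimises AIC = n·ln(WRSS/n) + 2(p + 1) over converged fits,
with WRSS floored at 1e−300 so exactly-fitting models get a finite, strongly
negative AIC and the parameter-count penalty still breaks ties. Note a
structural property of AIC selection on nested zoos: forms that nest another
with spare parameters (the 3-parameter rational contains the reciprocal
exactly) out-score the generating form in the usual chi-square exceedance
fraction of noise realisations (≈ 16% for one spare parameter), so exact
generative-model recovery saturates around 70–85%, not 100% — the selected
model is still an excellent *predictor*, which is what correction uses.

Correction applies the best fit per mode to every replicate value
(additive: x + f̂(SD_diff); multiplicative: x · ĝ(COV_diff), with an
additive-only fallback when a short-scan median is zero), then re-scores the
SDM per duration. Improvement bookkeeping (newly good / newly excellent per
technique) is reported at 5 s. Transfer between protocols applies the source
protocol's fitted parameters to the target protocol's noise estimates and
reports the percentage SDM increase.

## Numerical and design notes

* Percentages in category summaries are rounded to 2 decimals.
* The pipeline caches the simulate+extract stage per output directory, keyed
  by a hash of the phantom/extraction configuration, and is byte-reproducible
  from the master seed (restart jitter seeds derive from CRC32 of the feature
  id, not Python's randomised `hash`).
* The background-mean sanity check on simulated frames must account for the
  smoothing-induced spatial correlation (effective sample size ≈ N divided by
  the correlation volume of the PSF) and for PSF spill-in near inserts.
* Degenerate inputs: single-voxel ROIs are rejected before extraction; empty
  per-slice texture matrices are skipped from aggregation; a zero-variance
  reference feature is excluded from SDM with a degenerate-feature error.

## Known limitations

* Gaussian, spatially uniform, activity-independent noise; no reconstruction
  nonnegativity or iteration-dependent texture.
* Parametric insert geometry; no segmentation variability (masks are exact).
* The correction is fitted and evaluated on the same study (as in the
  emulated workflow); no train/test split is attempted.
* Background-noise-based correction and morphological features are out of
  scope by design.
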