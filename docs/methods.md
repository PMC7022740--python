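# Methods

This note documents the models, conventions and numerical choices behind
`tuberspec`, and what the synthetic test bed does and does not establish.

## The measurement model

A line-scan hyperspectral camera records a raw cube `I_raw` of
lines × samples × bands. Sensor offset and illumination are removed with
a dark cube `I_dark` (lens capped) and a white reference `I_white`
(≈100 % reflective Teflon), per pixel and band:

    I_c = (I_raw − I_dark) / (I_white − I_dark)

References may be full cubes or single-line profiles broadcast along the
scan axis, which is how line-scan systems actually record them.
Reflectance is **not** clipped at calibration — out-of-range values carry
information for preprocessing — but a warning is logged when more than
5 % of pixels fall outside [0, 1]; clipping happens only at rendering.

Slices are segmented from the black sample plate by thresholding the
band nearest 590 nm (where slice/background contrast is largest) at
reflectance 0.1. Requested wavelengths map to the nearest grid band,
ties resolved toward the lower band for determinism. No morphological
cleanup is applied by default; the segmentation is a plain threshold.

The noisy head and tail of the spectrum are discarded, keeping
477–947 nm inclusive (370 bands on the instrument grid; the generator's
full 380–1030 nm grid is built by extending that window at its own
spacing, so trimming recovers exactly 370 bands).

## Reference values

* Browning index: BI = 100 (x − 0.31)/0.172,
  x = (a\* + 1.75 L\*)/(5.645 L\* + a\* − 3.012 b\*).
* Lightness/yellowness ratio: L\*/b\*.
* Water content: WC = (w_wet − w_dry)/w_wet, g water per g wet matter.

Replicate chroma readings are averaged component-wise and BI and L\*/b\*
are computed **from the averaged** L\*, a\*, b\* — both are nonlinear in
the coordinates, so averaging per-reading indices would give a different
(wrong) number.

Outlier screening removes samples more than k = 3 sample standard
deviations from the per-target mean. This is a transparent default, not
a claim about how any particular laboratory screened its data; k is
configurable and k = ∞ disables screening.

The calibration/prediction split sorts samples by the target value
(ties broken by slice id) and sends the middle sample of every
consecutive triple to the prediction set; leftovers (n mod 3) go to
calibration. This yields a 2:1 ratio (234 → 156/78, 240 → 160/80),
guarantees the prediction range is bracketed by the calibration range,
and is invariant to input ordering.

## Preprocessing

Each spectrum is denoised by a level-3 Daubechies-9 ('db9') wavelet
decomposition with symmetric boundary padding; detail coefficients are
soft-thresholded at the universal threshold σ√(2 ln N), with σ estimated
from the median absolute deviation of the finest-level details
(MAD/0.6745). The thresholding rule is a standard parameter-free default
and is exposed in `PreprocessSpec`. Denoising runs before
normalization — normalizing first would rescale the noise floor.

Area normalization divides the spectrum by its sum. On a uniform grid
this is the trapezoidal-integral convention up to a constant factor, so
the two definitions coincide after normalization; the plain sum is used.
Every `SpectraMatrix` records its preprocessing provenance, and
`preprocess_matrix` refuses to run twice without an explicit force flag.

## Wavelength selection

**SPA** builds, from each start band, a chain that repeatedly appends the
band whose column has maximal norm after projection onto the orthogonal
complement of the already-selected columns — the least collinear
candidate. Chains are scored by cross-validated RMSE of an ordinary
least-squares fit on the selected bands (the classical SPA scorer is
MLR; the validation scheme here is the package's own CV folds), over
subset sizes 5–30; ties prefer fewer bands, then the lower start index.
Note that SPA chains are driven by **X only**: y enters solely through
the scoring step, so SPA finds informative bands only insofar as they
are also the least redundant ones. The unit tests plant signals inside
collinear band groups for exactly this reason.

**CARS** runs 50 Monte-Carlo iterations. Each iteration samples 80 % of
the calibration rows, fits PLS on the surviving bands (components by
inner 5-fold CV, capped at 10), ranks bands by |regression coefficient
on autoscaled X| (a common scale is required for the comparison), and
retains the count dictated by the exponentially decreasing function
r_i = a·e^(−k·i) calibrated so run 1 keeps all p bands and the final run
keeps 2. Adaptive reweighted sampling then competes the survivors:
weighted draws with replacement, deduplicated, topped up in coefficient
order so the retained count follows the EDF exactly (pure
sampling-with-dedup would undershoot the schedule). The subset with the
smallest ten-fold RMSECV across runs is returned. Run count and sampling
fraction are conventions of the published algorithm, surfaced in the
call signature and logged with every result.

Variable-reduction accounting reports 100·(1 − n_selected/n_total) to
one decimal.

## Regression

Both learners see autoscaled band columns, with scaling statistics taken
from the training rows of each CV fold only (leakage-free by
construction; for the RBF kernel, centering cancels in pairwise
distances, so per-fold scaling reduces to a per-fold weighting of
squared band differences).

**PLS** delegates to scikit-learn's NIPALS implementation; the number of
latent variables (default cap 20) minimizes ten-fold RMSECV, and the
final model is refit on all calibration rows. With all components on
full-rank X, PLS reproduces ordinary least squares — a test exploits
this identity.

**LS-SVM** solves the dual KKT system

    [[0, 1ᵀ], [1, K + I/γ]] [b; α] = [0; y],   K(u,v) = exp(−‖u−v‖²/σ²)

directly (the first row enforces Σα = 0; K + I/γ is positive definite
for γ, σ² > 0). The hyperparameter pair is found by a budgeted two-stage
search scored by ten-fold RMSECV: a 10×10 log grid over
γ ∈ [10⁻², 10⁶] and σ² ∈ [10⁻², 10³] × d̄ (d̄ = median squared pairwise
distance of the autoscaled calibration spectra), then a 10×10 refinement
spanning one coarse step around the incumbent — ≤ 200 of a 1000-
evaluation budget. The original method description names only "1000
repetitions of modeling optimization" without an algorithm; the budgeted
grid is this package's concrete realization and is fully configurable.

Every model carries a provenance record (band subset, expected band
count, preprocessing spec) and refuses input that does not match it.

## Evaluation

R² uses the conventional denominator Σ(yᵢ − ȳ)²; a variant with
Σ(ŷᵢ − ȳ)² in the denominator, occasionally seen in print, is available
behind `printed_denominator=True` but is not the default because only
the conventional form is mutually consistent with the RMSEP and SD
diagnostics reported alongside it. Standard deviations use the n − 1
denominator. RPD is the standard deviation of the **predicted** values
of the prediction set divided by RMSEP — the SD_P/RMSEP identity then
holds exactly within every report row. Qualitative labels: R² ≤ 0.60
poor, 0.61–0.80 capable, 0.81–0.90 good, > 0.90 excellent; RPD < 2.0
incapable, 2.0–2.5 usable, > 2.5 good; boundaries fall deterministically
into the lower-valued bin.

## Pixel-wise maps

Trained models are applied per pixel: masked spectra are trimmed,
preprocessed with the model's recorded spec, subset to its bands, and
predicted. P\* is the mean over masked pixels; the relative error
against a measured value is 100·|P\* − T\*|/T\*. Maps render through the
blue–green–red 'jet' scale with a shared color range (default: the
calibration-set range of the target) so maps are comparable across
slices; out-of-scale predictions are clipped for display only, and the
value array is serialized losslessly alongside the PNG.

## The synthetic test bed

The generator emulates the study conditions: 240 slices in eight
placement groups of 30, reflectance noise sd 0.005, and per-slice ground
truth spanning the observed value ranges (L\* 43.794–64.738,
a\* −3.096–+2.050, b\* 11.247–20.681, WC 0.753–0.879).

A latent browning level t ∈ [0, 1] maps affinely to (L\*, a\*, b\*) with
those extremes as endpoints (fresh at t = 0, fully browned at t = 1);
water content is drawn independently and uniformly. Pixel reflectance is

    R(λ) = baseline(λ) · exp(−Σ strength·Gaussian(λ)) + N(0, noise_sd)

with a smooth baseline peaking near 710 nm, a narrow pigment band at
678 nm and a broad browning band at 520 nm (both scaled by local
browning), and water bands at 760 and 930 nm scaled by local dryness
(1 − WC) — band depth is a monotone, invertible code for both latent
quantities. With browning > 0 the spectrum shows the characteristic
valley at 678 nm and local peak near 705 nm. Within-slice variation is a
smooth sum of three low-frequency 2-D cosines (amplitude
`pixel_field_scale`, default 0.05 in browning units, a tenth of that in
WC units) — gradual spatial gradients, no speckle. There is no empirical
anchor for within-slice statistics, so the scale is a configuration
parameter, not a claim. Raw/white/dark cubes are constructed so that
reflectance calibration inverts the construction exactly, and the
background carries ~0.02 reflectance so the 590 nm / 0.1 mask recovers
the generating footprint.

**What passing tests show — and what they do not.** Because all five
color indices are deterministic functions of the single browning latent,
the six regression targets in the synthetic study are mutually redundant
in a way real slices are not; recovery scores (R² ≈ 1 at noise 0.005)
demonstrate that the pipeline is correctly wired and information-
preserving, not that real potato data would reach any particular
accuracy. Real spectra add instrument drift, scattering variation,
biological covariance between color and water, and spatial artifacts
that the generator deliberately omits. Two further generator properties
to keep in mind: (1) the derived BI and L\*/b\* of synthetic slices span
wider ranges (BI ≈ 14.8–64.5, L\*/b\* ≈ 2.12–5.76) than observed data,
where the L\*, a\*, b\* extremes never co-occur on one slice; (2) the
dryness convention for the water bands is a sign choice — flipping it
would not change any recovery result.

## Problem sizes

The test suite and the acceptance script run the full study at 240
slices with 30-slice scenes (~170 pixels per slice, 511-band grid
trimmed to 370); module tests use coarser grids (e.g. 190 bands) and
smaller slice counts where the property under test does not depend on
scale. SPA oracle checks enumerate all start indices on matrices up to
8×6 over 100 seeds; CARS planted-signal recovery uses 100 bands × 40
samples over 20 seeds.

## Known limitations

* SPA's subset search evaluates every (start band, size) pair by CV-OLS;
  on very large grids this dominates runtime (it is vectorized but not
  incremental over subset size).
* The LS-SVM stores its full training kernel context; training is O(n³)
  per candidate fold solve and is intended for calibration sets of a few
  hundred samples, which is the method's natural scale.
* Scene simulation keeps whole cubes in memory; very large frames should
  be simulated in batches (as `simulate_dataset` does, 30 slices per
  scene).
* The ENVI I/O supports the subset of the format this pipeline produces
  (little-endian float32/uint16, BIL/BSQ/BIP, wavelength list in the
  header), not arbitrary vendor headers.
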