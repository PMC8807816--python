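# Methods

`drslayers` analyzes two-layered tissue from dual-distance diffuse
reflectance spectroscopy (DRS), optionally fused with ultrasound (US)
boundary features: it predicts the top-layer thickness by regression and
classifies the tissue type of each layer. Because no public measurement set
exists for this protocol, the package ships a first-class synthetic
generator that reproduces the statistical structure the analysis assumes;
everything downstream is exercised against it.

## Synthetic forward model

A probe with source-detector distances (SDD) of 2 and 6 mm feeds two
spectrometers, visible (400–1100 nm) and near-infrared (900–1700 nm). The
sampling depth of DRS is approximately the fiber distance, so we model the
detected reflectance of a two-layer medium as a modified Beer–Lambert
mixture with a top-layer path fraction

    f = min(1, d / SDD),
    R(λ) = S(λ; f) · exp(−[f·μ_top(λ) + (1−f)·μ_bot(λ)] · SDD),

where `d` is the top-layer thickness, `μ` is a sum of Gaussian absorption
bands, and `S` is a power-law scattering baseline (mixed with the same
fraction `f`). This is the simplest model that reproduces the two
qualitative facts the analysis relies on: dip depths of bottom-layer bands
decrease monotonically with top-layer thickness, and the bottom layer
vanishes from the signal once `d ≥ SDD`. It is deliberately phenomenological
— no photon transport — so absolute reflectance levels are not physical.

**Consequence worth knowing:** because `f` saturates at `d = SDD`, the
phantom thickness ramp (0–15 mm) is only resolvable up to the fiber
distance; full-spectrum regression errors on the synthetic phantom are
therefore dominated by the indistinguishable `d ≥ SDD` locations (clearly
visible when comparing the 2 mm and 6 mm arms). Real low-absorbing phantoms
retain some sensitivity beyond the SDD, which this model intentionally does
not emulate.

Band placement encodes the field's contrasts: the phantom bottom layer
absorbs at 637 nm (a patent-blue analogue under a top layer transparent at
that band); fat absorbs more strongly near 935 and 1200 nm than near 985 nm;
muscle, water-dominated, the reverse; both share the ~1450 nm water
overtone. Amplitudes (0.05–0.55 mm⁻¹) were fixed once so that class spectra
overlap but remain separable — default-condition classification should score
high but below 1.0. Raw counts add a dark offset (100 counts),
detector-specific gains (4000/3000 counts), additive Gaussian noise
(`noise_sd`, default 0.01 of nominal gain), and a per-acquisition
multiplicative gain jitter (SD 0.05) that hits the measurement but not the
white reference — this is what the 800 nm normalization must cancel. The
white reference encodes the nominal gain exactly, so a noise-free
acquisition calibrates back to the model reflectance to machine precision.

Study designs: the phantom preset is 15 locations × 4 orientations × 3
repeats = 180 measurements with a linear 0–15 mm thickness ramp across
locations (orientations/repeats differ only in noise). The animal preset has
two strata — fat-on-muscle and muscle-on-fat — with thicknesses drawn from
truncated normals (2.81 ± 1.90 mm and 3.25 ± 1.57 mm respectively, clipped
to [0, 6) mm), one forced 0 mm (single-layer) sample per stratum, and one CV
location per sample. A flag can jitter the *recorded* ground truth
(SD 0.27 mm) to emulate manual US thickness-reading error; it is off by
default so that reported errors isolate the estimator.

The US image generator draws a 160 × 96 grid at 0.05 mm axial pixel
spacing: a bright contact stripe at row 10, a layer-intensity step at
`contact_row + round(d / pixel_mm)` (fat rendered brighter than muscle),
unit-mean gamma multiplicative speckle (coefficient of variation
`speckle_scale`, default 0.15), and optionally bright fibrous streaks inside
the top layer to exercise the k-best path logic. It does not emulate beam
physics, attenuation with depth, or curved-probe geometry — passing tests
show the segmenter recovers step-like boundaries under speckle, not that it
handles clinical image quality.

All randomness flows from one integer seed through `numpy.random.SeedSequence`
spawning; identical seeds give bit-identical datasets.

## Preprocessing

Raw counts are calibrated as `(R_meas − R_dark) / (R_white − R_dark)`; a
wavelength where white and dark coincide raises an error naming it. The two
detectors are stitched at 1000 nm (midpoint of their 900–1100 nm overlap):
the NIR segment is multiplied by the single scalar that makes the detectors
agree at the crossover (detector throughputs are independent; the rescale
can be disabled in config), then both segments are linearly resampled to the
canonical grid 400, 401, …, 1599 nm (1200 points; 1600–1700 nm discarded for
poor SNR). Finally the spectrum is divided by its value at the exact 800 nm
grid point — a region without significant tissue absorption — which cancels
global intensity differences. Negative calibrated values (possible under
noise) are kept, not clipped; the feature extractors are max−min based and
tolerant. Feature extractors index windows by wavelength, never by position.

## Spectral features

*Peak (dip-to-peak) features*: max − min reflectance in the windows
920–960, 960–1150 and 1150–1325 nm (endpoints inclusive; the grid contains
them exactly), bracketing the 935/985/1200 nm fat and water bands. Three
values per SDD; six after concatenating 2 mm then 6 mm.

*Wavelet features*: six iterations of {convolve with the 8-tap Symlet
scaling (low-pass) filter under half-sample symmetric extension, decimate by
2}, applied each time to the previous approximation; the level-6
approximation of a 1200-point spectrum has 25 coefficients via the length
recursion `n → floor((n+7)/2)`: 1200 → 603 → 305 → 156 → 81 → 44 → 25.
Fifty features after dual-distance concatenation. The 8-tap filter is
`sym4`'s low-pass; an 8-tap length is also the only choice consistent with
the 1200 → 25 count under the standard symmetric-extension length rule (a
16-tap Symlet gives 33). Computation uses PyWavelets; the test suite checks
each level against an independent convolve-and-decimate reference.

## Ultrasound segmentation

The image is smoothed with a 5×5 Gaussian (σ = 1), and the vertical
first-difference magnitude is min-max rescaled to [0, 1] (absolute value,
since fat→muscle and muscle→fat transitions must both score). Pixels are
graph nodes; an edge between pixels `a, b` costs `2 − (g_a + g_b) + w_min`
with `w_min = 1e−5`, so high-gradient pairs are cheapest. One column of
gradient-1 nodes is padded on each side; Dijkstra runs from the padded
upper-left to the padded bottom-right corner. Vertical moves are free only
inside the pad columns; image columns are traversed strictly left-to-right
with row steps of at most one (8-connected), so a path visits exactly one
pixel per column. Cost ties are broken deterministically toward the
shallower path (lexicographic (cost, row-sum) relaxation inside Dijkstra) —
the need for an exact, deterministic tie-break is why the search is a small
in-package heap implementation rather than a library call; it is verified
against exhaustive path enumeration on small grids.

The contact surface is the best path over the top 20 rows only (flagged
low-confidence when the on-path gradient stays below 0.1). Candidate tissue
boundaries are found below the contact path plus a 3-row guard band (so the
bright stripe is not re-detected); after each selection the path's pixels
±2 rows are excluded and the search re-runs, yielding up to k = 3 paths in
non-decreasing cost order. This node-exclusion re-run is not a true
k-shortest-paths algorithm; it matches the intended "distinct candidate
boundaries" semantics and is simple to verify. Guard band and margin are
config-exposed. At the center column (`floor(width/2)`), the descriptor is:
three contact-to-boundary distances in mm (a missing path contributes the
full image depth as a sentinel) and the three rescaled gradient values at
the boundary pixels (0 for missing paths).

## Evaluation protocol

Folds are drawn over *locations*: distinct location ids are shuffled and
split into 10 nearly equal blocks, so repeated acquisitions of one spot
never straddle the train/test split. The whole procedure is repeated for 20
iterations with fold seed `base_seed + iteration`; features are z-scored
with training-fold statistics (zero-variance features dropped with a
warning).

Regression models: linear SVR (ε-insensitive loss, C = 1, ε = 0.1) and
Gaussian process regression with an exponential kernel — Matérn ν = 1/2,
i.e. the Ornstein–Uhlenbeck kernel — times a constant, plus a white-noise
term; hyperparameters by marginal-likelihood maximization with 3 restarts,
seeded. A predict-the-training-mean baseline is included for skill checks
(its expected MAE is the target's mean absolute deviation, ≈ SD·√(2/π)
under normality). The report gives mean ± SD of the absolute error pooled
over all held-out predictions of all iterations, per-sample mean
predictions, and Bland–Altman bias with ±1.96·SD limits of agreement.

Classification: SVM with an inhomogeneous quadratic polynomial kernel
(degree 2, coef0 = 1, C = 1), fat as the positive class. Accuracy, MCC
(defined 0 at any zero marginal), rank-based AUC (ties count ½),
sensitivity and specificity are computed per iteration over that iteration's
pooled held-out predictions, then averaged across iterations (SD across
iterations kept alongside); the ROC curve is vertically averaged on a
101-point false-positive-rate grid with an SD band. If a fold draw leaves a
training fold single-class, folds for that iteration are redrawn with a
shifted seed and the event is logged.

Paired model comparisons use the two-sided Wilcoxon signed-rank test on
per-sample absolute errors averaged over iterations (zero differences
removed; exact null for ≤ 25 untied pairs, otherwise the tie-corrected
normal approximation), at a 0.05 threshold without multiplicity correction.

## Problem sizes and numerical choices

The acceptance script (`scripts/acceptance.py`) runs the animal arms at the
full protocol (100 samples per stratum, 10 folds, 20 iterations) and the
phantom full-spectrum GPR arm at 5 iterations — the 1200-feature GPR
dominates runtime and its MAE is stable across iterations well before 20.
Property tests use smaller designs (e.g. 30 samples per stratum, 2
iterations) chosen as the smallest sizes at which the checked orderings are
stable. Noise-degradation checks use the five levels 0, 0.01, 0.03, 0.08
and 0.2 (relative count noise); beyond ~0.2 the regression error saturates
at the predict-the-mean level, so higher levels would no longer order.

## Known limitations

- The forward model's hard path-fraction saturation under-states real
  sensitivity beyond the fiber distance (see above); synthetic phantom
  full-spectrum errors are not comparable to measurements on physical
  phantoms.
- The generator's class spectra differ more cleanly than real tissue;
  synthetic classification scores are an upper bound on what identical code
  achieves on measured data.
- The US generator produces flat, horizontal layers; the segmenter's
  8-connected single-step paths would need steeper connectivity for highly
  oblique boundaries.
- Spectral resolution of the simulated detectors is a uniform 1 nm grid;
  real spectrometer line-spread functions are not modeled.
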