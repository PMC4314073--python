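# Methods

## Signal model

The pipeline treats each 5×5-pixel cluster of a fundus video as a
photo-plethysmographic sensor. Transmitted green intensity *I* is
mapped to absorbance `A = 68 · (−log10(I / I_max))`, with intensities
normalised by the camera full scale so full transmittance maps exactly
to 0 and zeros clamped to half the least count (`1/(2·I_max)`) to keep
the logarithm finite. The factor 68 is a fixed calibration constant
that nominally converts decadic absorbance to microns of half optical
path length through haemoglobin (550 nm extinction, physiological
haemoglobin concentration, light traversing the vessel twice); the
resulting values are treated as arbitrary units throughout, and no
claim of absolute micron accuracy is made.

Each cluster's mean absorbance series is modelled as

    y(t) = β₀ + Σ_{k=1..H} a_k cos(2πkφ(t)) + b_k sin(2πkφ(t)) + s(t) + ε,

where φ(t) ∈ [0, 1) is cardiac phase and s(t) is a continuous
piecewise-linear function of absolute time (centred time plus one hinge
per interior beat onset, i.e. one slope per cardiac cycle). The spline
exists to absorb slow drift from patient movement and illumination
change; consequently the **pulsation amplitude is defined as the
peak-to-trough range of the periodic component only**, excluding
intercept and spline. Including the spline in the extremum search
would re-import exactly the artefact the term is there to remove.

### Assumptions

- Pulsation is periodic in cardiac phase; heart-rate variability is
  handled by normalising phase per cycle (each interval between
  consecutive beat onsets maps to [0, 1)), so a cycle that runs 10%
  long is stretched rather than smeared. Frames before the first or
  after the last onset belong to no complete cycle and are excluded
  from regression.
- Between-frame motion is affine (translation, rotation, shear,
  isotropic scale); non-rigid deformation and torsional eye movement
  are out of scope.
- Noise is independent between frames after drift removal; fits are
  ordinary least squares.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `scale_factor` | 68 | units/decade | fixed calibration constant, adopted verbatim |
| `cluster_size` | 5 | px | raster resolution of the amplitude map (5:1 to pixels) |
| `n_harmonics` (H) | 2 | — | fundamental + 2nd harmonic capture the systolic peak and dicrotic shoulder; configurable 1–4 |
| `phase_grid` | 1000 | — | grid for extremum bracketing; single-fit extrema are refined by root-finding on the analytic derivative |
| threshold sweep | 0..40 | units | integer amplitude scale covering ≈99.98% of observed values; amplitudes above 40 still count as "> threshold" |
| heat-map scale | 0–40 | units | fixed across runs for comparability; values above saturate |

Detection is **strict**: a cluster is pulsatile at threshold *T* iff
amplitude > *T*; equality is non-pulsatile. Ideal-threshold ties break
toward the lowest threshold (favours sensitivity, consistent with the
no-region-missed reading of the validation). Observer-outline regions
are 8-connected components of the cluster grid, since hand-drawn
outlines routinely produce diagonal adjacency. The eye-level critical
amplitude is the minimum over region maxima: it is the unique value
such that integer thresholds at or below it retain every region while
any threshold above it loses at least one (generic for non-integer
region maxima).

The empirical AUC is the trapezoidal area under the anchored ROC
polyline: the per-threshold (FPR, TPR) points plus anchors (0,0) and
(1,1), sorted into sweep order (both rates are non-increasing in
threshold, so lexicographic sorting recovers it). Points sharing an
FPR form vertical, zero-width segments; averaging them instead would
under-count perfectly separable curves.

## Registration

Frames are registered to a reference frame (default: the first) by
minimising the mean-squared green-channel difference over affine
parameters, coarse-to-fine over a 4×/2×/1× image pyramid (Powell's
method; phase-correlation seeds the translation at the coarsest
level). Two numerical choices matter:

- **Cubic interpolation at the finest level.** Bilinear-interpolated
  MSE has spurious local minima at integer translations (interpolation
  blurs the moving image at fractional shifts, raising MSE against a
  sharp reference); sub-pixel refinement reliably stalls there. Cubic
  interpolation removes the trap; measured accuracy on noise-free
  synthetic jitter is ≈0.15 px and ≈0.1°, against acceptance bounds of
  0.5 px and 0.2°.
- **Explicit validity masks.** Warped pixels that fall outside the
  camera view are flagged, not filled; the subsequent crop is the
  largest axis-aligned rectangle valid in *every* frame (histogram-
  stack maximal-rectangle algorithm), so no interpolated garbage
  reaches the regression.

The movement index is `sqrt(max_dx² + max_dy²)` where `max_dx`/`max_dy`
are the spreads (max − min) of the recovered per-frame translations —
the displacement between the two most displaced frames. Rotation and
shear are deliberately excluded: translation dominates inter-frame eye
movement, and the index is meant as a per-recording wobble summary,
not a full motion norm. An `euclidean` model (translation + rotation
only) is available when shear/scale freedom is unwanted.

## Harmonic fitting implementation

Phase is a per-frame quantity, so every cluster shares one design
matrix; the package solves a single least-squares problem for all
clusters simultaneously (`numpy.linalg.lstsq` with the stacked
response matrix) rather than looping per cluster. A cluster whose
series is non-finite is flagged, assigned amplitude 0, and counted; a
run aborts if more than 10% of clusters fail. For the per-cluster map
the periodic extremum search uses the 1000-point phase grid directly
(with H ≤ 4 the grid error is < 0.01% of the amplitude); the
single-series `amplitude_from_fit` additionally refines extrema by
Brent root-finding on the analytic derivative, and the two paths are
cross-checked against a 10⁶-point grid in the tests.

## Synthetic scenes

The generator renders the recording conditions the pipeline is built
for: three cardiac cycles at 25 fps, a bright vignetted disc,
curvilinear dark vessels with 1-px feathered edges, per-vessel
sinusoidal absorbance modulation (optional second harmonic and phase
offset), multiplicative sinusoidal illumination drift, per-frame
affine jitter, Gaussian sensor noise in intensity space, and 8-bit
quantisation. The waveform is normalised to unit amplitude so a
vessel's `amplitude` parameter *is* its per-pixel peak-to-trough
absorbance in map units, making recovery tests self-calibrating;
ground truth records the exact per-pixel peak-to-trough range of the
composite periodic field (dense-grid evaluation of the accumulated
harmonic coefficient maps), its 5×5 cluster means, the any-pixel
pulsation mask, and the applied jitter transforms.

Preset study conditions (200×200 px, 75 frames, beat onsets at 0, 1,
2, 3 s): `clean` (no nuisance), `noisy` (σ = 2 intensity levels),
`drift` (2% illumination modulation, giving a whole-frame intensity SD
inside the clinically observed 0.5–3.5 band), `wobble` (±6 px, ±1°
jitter — comparable, after scaling from the ~405×502-px clinical
frames to 200 px, to the recorded 22–181 px movement range) and
`separable`. The separable preset uses hard-edged bars snapped to the
5-px cluster grid: every annotated cluster is then fully covered, so
cluster amplitudes are ≥ 12 units on the mask and 0 off it and the
ROC is perfectly separable by construction. With feathered curvilinear
vessels this would not hold — OR-pooling marks clusters containing a
single low-weight edge pixel whose mean amplitude is a few hundredths
of a unit.

What the generator does **not** emulate: physiological pulse-waveform
detail, optics (point-spread function, specular reflexes), saccades
beyond affine jitter, spatially varying noise, vessel caliber change
as geometry (pulsation is purely an absorbance modulation). Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to every property of
clinical recordings.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline at 200×200×75
(amplitude/ROC paths, ~1 s per fit) and register 8–10 jittered
150×150 frames (~1 s per frame); the bundled 26-eye per-eye table
supplies the cohort-summary checks. All stochastic components draw
from `numpy.random.default_rng` seeded explicitly; a scene spec with a
fixed seed renders bit-identically, and repeated runs of the
command-line workflow on the same inputs produce byte-identical CSVs.

## Known limitations

- The amplitude scale is relative; comparing absolute units across
  cameras or gamma settings requires the same normalisation and
  calibration constant.
- The spline absorbs only piecewise-linear drift; drift with
  substantial power at the cardiac frequency aliases into the
  harmonics (illumination drift near one cycle per beat is the
  worst case).
- Registration assumes the scene is mostly static apart from the
  pulsatile absorbance; gross content change (blinks, large saccades)
  surfaces as registration failure naming the frame rather than being
  repaired.
- Cohort summaries implement the median + back-transformed log-scale
  t-interval; mixed-effects modelling of explanatory variables is out
  of scope.
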