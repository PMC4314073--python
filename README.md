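# pulsemap

Objective mapping of retinal vessel pulsation from cardiac-gated fundus
video.

Retinal venous pulsation is a long-standing clinical sign: it disappears
with raised intracranial pressure, retinal vein occlusion and in many
glaucoma patients, but its assessment is subjective and needs a skilled
observer. `pulsemap` implements a video photo-plethysmographic
alternative: from a short fundus video (nominally 25 fps, three cardiac
cycles) plus the beat-onset times of each cardiac cycle, it produces a
spatial map of pulsation amplitude and the ROC framework needed to
validate such maps against expert observers' outlines.

## Method

For each frame the green channel (haemoglobin absorbs strongly near
550 nm) is extracted, frames are affine-registered to a reference frame
and cropped to the commonly visible region, and each pixel's intensity
*I* is converted to an absorbance-like quantity via the Beer-Lambert
law:

```
A = 68 · (−log10(I / I_max))
```

where the fixed factor 68 places *A* on a nominal half-path-length
scale (arbitrary units). The image is tiled into 5×5-pixel clusters;
each cluster's mean absorbance time series *y(t)* is fit by ordinary
least squares on a cardiac-harmonic basis with a movement/drift term:

```
y(t) = β₀ + Σ_{k=1..H} [ a_k cos(2πk φ(t)) + b_k sin(2πk φ(t)) ] + s(t) + ε
```

with φ(t) the cardiac phase in [0, 1) (per-cycle normalised between
consecutive beat onsets), H = 2 harmonics by default, and *s(t)* a
continuous piecewise-linear spline in absolute time with knots at the
interior beat onsets. The cluster's **pulsation amplitude** is the
peak-to-trough range of the fitted periodic component — the quantity
rendered as a heat map on a fixed 0–40 unit scale.

Validation against an observer's hand-drawn outline: the outline is
reduced 5:1 by OR-pooling (a cluster is pulsatile if any of its 25
pixels is annotated), the map is thresholded at every integer amplitude
0..40 (strictly "amplitude > threshold" counts as detection), and the
per-threshold confusion counts yield an empirical ROC curve and AUC,
the **ideal threshold** (maximum sensitivity × specificity product) and
each outlined region's **critical amplitude** (the maximum amplitude
inside the region — the threshold ceiling above which the region would
be missed entirely). Cohen's kappa quantifies inter-observer agreement,
and cohort-level results are summarised by medians with log-scale
t-intervals.

A synthetic-scene generator (`pulsemap.synth`) renders pulsatile
fundus-like videos — curvilinear dark vessels on a bright disc,
sinusoidal cardiac absorbance modulation, illumination drift, affine
jitter, sensor noise — with exact per-cluster ground truth, so the
whole pipeline is testable without clinical recordings.

## Worked example

```python
from pulsemap import (PulsationMapper, generate, preset_scenes,
                      roc_sweep, rates, confusion, segment)

stack, beats, truth = generate(preset_scenes(seed=0)["noisy"])
mapper = PulsationMapper(n_harmonics=2).fit(stack, beats)
amp = mapper.amplitude_map_.amplitude
print(f"clusters analysed: {mapper.n_clusters_}")
print(f"amplitude range: {amp.min():.2f}-{amp.max():.2f} units")
res = roc_sweep(mapper.amplitude_map_, truth.cluster_mask)
print(f"AU-ROC vs ground-truth mask: {res.auc:.3f}")
print(f"ideal threshold: {res.ideal_threshold} units")
print(f"critical amplitude (eye level): {res.critical_amplitude:.1f} units")
```

prints

```
clusters analysed: 1600
amplitude range: 0.01-13.46 units
AU-ROC vs ground-truth mask: 0.912
ideal threshold: 1 units
critical amplitude (eye level): 13.5 units
```

The 200×200-px scene tiles into 1600 clusters. Vessel clusters carry
amplitudes up to ~13.5 units (two vessels with 10- and 6-unit
peak-to-trough modulation, plus their crossing) against near-zero
background, so the map separates pulsatile from quiet clusters almost
perfectly (AUC 0.91 against the strict any-pixel ground-truth mask,
whose vessel-edge clusters contain only a sliver of vessel). The eye's
critical amplitude of 13.5 units says any detection threshold above
13.5 would miss the strongest region entirely; the ideal threshold of
1 unit sits far below it.

The same pipeline is scriptable from a shell:

```
pulsemap simulate --preset noisy --out run/
pulsemap analyze  --stack run/stack.tif --beats run/beats.csv --skip-alignment --out run/
pulsemap validate --amplitude run/amplitude.csv --mask run/truth_mask.png --out run/
pulsemap summarize --eyes per_eye_results.csv --out run/
```

producing `amplitude.csv`, `heatmap.png`, `roc_<observer>.csv`, an
agreement overlay (yellow = detected ∧ observed, green = detected only,
red = observed only), `summary.json` and a run log.

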