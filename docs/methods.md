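# Methods

`nvckit` quantifies neurovascular reactivity from two in-vivo imaging
modalities: wide-field laser speckle contrast imaging (LSCI) of cortical
perfusion during whisker stimulation or a CO₂ challenge, and two-photon
time series of single plasma-labelled vessels. Both pipelines are fully
declarative — every choice a human would make interactively (region of
interest, measurement lines, excluded frames) is an explicit input — so a
run is reproducible and investigator-independent.

## LSCI pipeline

**Model of the data.** A perfusion stack is a time-major array of arbitrary
perfusion units sampled at 4.4 Hz. The signal at each pixel is treated as a
baseline level modulated by (i) slow instrumental/physiological drift,
(ii) a stimulation-locked response, and (iii) speckle-like multiplicative
noise. All reported quantities are ratios (percent change), so the
absolute unit of perfusion cancels everywhere; a scale-invariance property
test asserts this.

**Re-alignment.** Brain motion from heart beat and breathing shifts frames
by a few pixels. Each frame is rigidly translated by the integer shift
(search radius 10 px) maximizing its cross-correlation with the pixelwise
median frame after mean subtraction; border pixels exposed by the shift
become missing (NaN). Subpixel registration is deliberately not attempted:
downstream windows average tens of frames and the response footprint spans
many pixels. Alignment is off by default in the CLI (the synthetic data are
already registered) and enabled with `align_frames: true`.

**Drift filtering.** Slow drift is removed with a high-pass Chebyshev
Type I filter of order 2, passband edge 0.004 Hz, passband ripple 0.5 dB
(ripple is a conventional engineering default; the response math is
ratio-based and insensitive to it). Zero-phase application matters here —
onsets must not shift — and at a 0.004 Hz edge the impulse response spans
hundreds of samples, so padding-based forward-backward filtering leaves
asymmetric edge transients. `filter_trace` therefore (1) subtracts the
straight line through the trace endpoints, which is pure drift by
construction and is never re-added, and (2) applies the squared Chebyshev
magnitude response in the frequency domain on an even mirror extension of
the residual. This is transient-free, exactly symmetric for symmetric
inputs, and annihilates DC; single-pass DC attenuation measured at
10⁻⁶ Hz is ≈ 141 dB.

**Stimulation detection.** The filtered ROI-mean trace is thresholded by
Otsu's method on a 256-bin histogram. Maximal supra-threshold runs become
epochs after bridging sub-threshold gaps shorter than 2 s and discarding
runs shorter than 5 s (stimulations last 60 s; these two defaults only
suppress noise chatter). The onset is the first supra-threshold sample. A
verification plot (trace, threshold, detected spans) is always written so
the detection can be checked visually. A near-constant trace has no
meaningful Otsu split and yields no epochs, with a warning. Externally
supplied event markers (e.g. the capnograph-defined 5-min CO₂ window)
override detection when present.

The Otsu threshold is computed in-package and returns the *upper bin edge*
of the optimal split rather than the split bin's center. With `value >
threshold` classification, a bin-center threshold misclassifies any
histogram spike inside the split bin — exactly the situation at the
partial-intensity rim of a smoothed vessel image, where one value is
shared by the whole edge population. The bin-edge convention realizes the
partition that actually maximizes the between-class variance; tests verify
it against an exhaustive search.

**Response maps.** Per ROI pixel, the response is
`100 · (mean(response window) − mean(baseline window)) / mean(baseline
window)` on the raw trace, with the response window +10 to +30 s after the
onset (skipping the ramp-like initial rise) and the baseline window −40 to
−10 s before it. The per-epoch local baseline makes the map insensitive to
slow drift. Pixels outside the ROI, and pixels with a non-positive
baseline, are missing. Maps are cropped to the circular ROI's square
bounding box and resampled bilinearly to a fixed 120 × 120 grid; missing
values are propagated by normalized convolution (values and a validity
weight resampled separately, output pixels with under half support stay
missing). On the common grid, maps average across stimulations, then
across animals, ignoring missing values; input order cannot change the
result (summation runs in a canonical order).

**Scalar metrics.** On the ROI-mean trace expressed as percent of the
epoch baseline — numerator drift-filtered, denominator the raw baseline
level — three scalars are computed per epoch: the peak (maximum within the
epoch, first occurrence), the slope `(peak − baseline mean) / (t_peak −
t_baseline_end)` (the same construction as the vessel slope below, with
the baseline window mean ≈ 0), and the trapezoidal area under the curve
from onset to offset + 120 s recovery (bounds configurable; the recovery
tail captures the post-stimulus return to baseline).

## Vessel diametry

**Binarization.** Each frame is smoothed with a Gaussian (σ = 1 px) and
thresholded per frame by Otsu, giving 1 = vessel, 0 = background; a fixed
global threshold is available when strict cross-frame comparability is
preferred. A constant frame binarizes to background with a warning.

**Diameter.** A measurement line is drawn perpendicular across the vessel.
It is thickened to 4 parallel voxel lines (perpendicular offsets −1.5,
−0.5, +0.5, +1.5; generally k symmetric offsets at unit spacing), each
rasterized with Bresenham using half-up rounding so even thicknesses land
on distinct voxel rows. Per line, the diameter is the count of vessel
voxels multiplied by the line's sampling step (Euclidean length over point
count − 1) and the voxel size; the frame diameter is the mean over the
parallel lines. The step factor is 1 for axis-aligned lines — plain voxel
counting — and √2 for diagonals, without which an oblique crossing would
understate the diameter by up to ~30 %. Averaging the parallel lines damps
single-voxel dropouts caused by passing erythrocytes from a full voxel to
1/k voxel. Excluded frames are missing; frames may be excluded manually
and/or by an automatic screen (frame-to-frame Pearson correlation < 0.8,
or foreground-mean / background-std after a provisional Otsu split < 2).

**Peak detection.** A baseline-tracking state machine with three
user-facing parameter groups: baseline length (10 frames), opening
threshold (5 % above baseline) and a hysteresis close rule (3 consecutive
frames below 2 % above baseline, preventing chatter on noisy plateaus).
The baseline is the mean of the next 10 valid frames; its timestamp is
that of the last frame entering the mean. After a peak closes the baseline
is recomputed immediately from the following frames — no refractory gap —
and detection continues. Missing frames are skipped throughout and do not
reset the close counter. Each peak records

    percent change = 100 · (d_max − d_base) / d_base
    slope          = ((d_max − d_base) / (t_max − t_base)) / d_base

i.e. the rise rate normalized by the baseline diameter (units s⁻¹). A
maximum landing exactly on the baseline timestamp leaves the slope
undefined (NaN, warned). Per-vessel-class summaries (pial, penetrating,
capillary) aggregate mean/max percent change and slope across all peaks of
all lines in a class.

## Synthetic data

`simulate_lsci` renders per-pixel traces `baseline · (1 + drift(t) +
blob(r,c) · response(t)) · (1 + ε)`, ε ~ N(0, σ). Defaults emulate the
whisker-stimulation protocol: three 60-s stimulations with 120-s rest
intervals (onsets 60/240/420 s), amplitude 10 %, a Gaussian spatial
footprint (σ = 10 px) on a 64 × 64 field, linear drift of 5 % per 10 min,
and 2 % multiplicative noise at 4.4 Hz. The response time course is a ramp
to amplitude followed by a boxcar; the default ramp is 0 s (a step), which
keeps the ground-truth onset unambiguous for onset-accuracy scoring —
ramped responses are exercised explicitly in tests. Noise is multiplicative
because speckle contrast noise scales with signal; the generator does not
model speckle statistics or optics.

`simulate_vessel` renders an anti-aliased bright tube (intensity 200 on
background 10) whose width follows `w(t) = w₀ · (1 + dilation(t)/100)`,
with optional dark intraluminal blobs (erythrocytes), rigid-jittered
frames and additive Gaussian noise (default σ = 9.5, i.e. 5 % of the
dynamic range), one frame per 2 s. The default tube is 40 voxels wide with
its axis on a voxel boundary, so 5/10/20 % dilations give exact even voxel
widths (42/44/48) and binarized voxel counting has an exact ground truth;
odd widths would leave two half-covered edge pixels precisely at the
threshold decision boundary. Both generators are pure functions of their
config including the seed.

What the generators do *not* emulate — real speckle statistics, vessel
curvature and branching, focus drift, physiological oscillations
(heartbeat, vasomotion), photon noise — bounds what passing tests show:
they validate the numerics and the contracts of the pipeline, not its
robustness to every property of real recordings.

## Numerical conventions and edge cases

- Missing data is NaN everywhere; averages are over available values.
- Windows are inclusive at both bounds with a 10⁻⁶-sample guard against
  floating-point jitter at sample boundaries.
- Peak/maximum ties resolve to the first occurrence.
- Map resampling uses skimage's half-pixel-center convention, order 1.
- `write_heatmap` renders NaN as the colormap's bad color and rejects ±inf
  with the offending pixel index; the numeric CSV next to each PNG is the
  lossless record, the PNG (fixed 0–15 % scale by default) is for viewing.
- Problem sizes in tests and in `scripts/acceptance.py` (600-s LSCI
  cohorts of 3 animals at 64 × 64; 240-frame vessel movies at 128 × 128)
  are chosen so a full verification runs in minutes on one CPU while
  leaving every estimator's error well inside the asserted bounds.

## Known limitations

- Alignment is integer-pixel and rigid; rotation or warping is out of scope.
- The AUC of a CO₂ response is computed on the drift-filtered trace; for
  events approaching the filter time constant (~250 s) the high-pass sag
  attenuates the absolute AUC, so AUC comparisons should use identical
  filter settings.
- Vendor container formats (Perimed `.dat`, Zeiss LSM) are not parsed;
  data must be exported to TIFF or raw float32 + JSON sidecar.
- Diametry assumes a locally straight vessel across the measurement line;
  strongly curved or branching vessels need shorter lines.
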