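# Methods

## The measurement model

A larva driven by cyclical optogenetic stimulation contracts its body wall
while the light is on and relaxes while it is off. On video, contraction
shortens the animal's outline, so the perimeter of the segmented body is
used as the contraction readout: it reflects longitudinal shortening
directly and, unlike area or centroid speed, is comparatively insensitive
to rearing (the animal lifting its head off the substrate).

The analysis assumes: one animal in frame; the animal darker than the
(possibly unevenly lit) background; a frame-synchronous indicator LED whose
ROI intensity is bimodal between stimulus-off and stimulus-on plateaus; and
a stimulus program of the form *delay, then n × (on, off)*.

## Segmentation chain

`preprocess.segment_frame` composes, in order:

1. **Gaussian blur**, sigma = radius, default radius 1 px. The
   radius-to-sigma convention is fixed here (σ = r) because drawing-tool
   conventions vary; the only requirement is that it is stated and constant.
2. **Rolling-ball background subtraction**, default radius 50 px,
   implemented as a grayscale *opening* with a ball-shaped structuring
   element: the erosion pass is the classic ball-apex lower envelope
   (delegated to `skimage.restoration.rolling_ball`), followed by a
   dilation with the same element that lifts the envelope back onto the
   surface. The full opening — not the erosion alone — is required for the
   defining property that a smooth, object-free illumination gradient is
   reproduced exactly (zero residual away from borders) at any ball radius,
   while objects narrower than the ball survive in the residual. For a
   dark-on-light scene the frame is photometrically inverted first (white
   level = dtype max for integer frames, frame max for float), so the
   animal is always a positive residual. For radii ≥ 16 px the ball rolls
   on a 2–8× downsampled copy (factor by radius, as in common practice for
   large balls) and the background is bilinearly resampled back; tests use
   the exact path against an independently computed scipy grayscale
   opening.
3. **Otsu threshold** of the residual: exhaustive maximization of
   between-class variance over a 256-bin histogram (integer gray levels for
   8-bit input; other dtypes are range-scaled first), dark class `v ≤ t`,
   ties broken toward the lowest threshold. Implemented directly so the
   integer-threshold convention is exact; `skimage.filters.threshold_otsu`
   serves as an independent cross-check in tests. The threshold is computed
   per frame by default, or once on a reference frame (`freeze_threshold`),
   since which of the two the original interactive workflow used is not
   knowable and both are defensible.
4. **Binarization** with foreground = animal, regardless of how a viewer
   would display it.

A frame with no structure above background yields an empty mask, not an
error — a transiently absent animal is data, and the tracker records the
frame as invalid.

## Tracking

Components are 8-connected (a strongly contracted larva can be one diagonal
pixel wide). Candidates must pass area gates (defaults 100–100 000 px²,
generous on purpose; the gates exist to reject the indicator dot and
speckle). Linking is nearest-centroid to the last valid frame with a
per-frame displacement gate (`max_jump`, default 20 px) that widens
linearly across gaps; the first valid frame seeds on the largest candidate.
Invalid frames carry missing values — interpolation happens only inside
cycle windows, for extremum-finding, for gaps of ≤ 3 frames; a longer gap
inside an on-window invalidates (flags) that cycle rather than inventing
its extremum.

**Perimeter estimator.** The boundary is traced as a closed 8-connected
chain (Moore tracing) and measured with Vossepoel–Smeulders corrected
weights: 0.980 per axial step, 1.406 per diagonal step, −0.091 per corner.
The plain 1/√2 chain length overestimates smooth digital contours by
5–6 %, which would leak directly into amplitude estimates; the corrected
weights keep digitized disks of radius 10–50 within ~2 % of 2πr. The
convention's fixed points: an axis-aligned w × h rectangle measures
0.980·(2(w+h)−4) − 4·0.091, and an isolated pixel is assigned 3.556 (the
weight of the minimal closed 4-step chain).

## Stimulus decoding and alignment

The indicator-ROI mean is clustered into two plateaus (deterministic 1-D
two-means initialized at the extremes); the decoding threshold is the
plateau midpoint, and a frame is "on" iff its ROI mean is strictly above
threshold (boundary frames count as off — arbitrary but fixed). A trace
whose plateaus are closer than twice the summed within-plateau spreads is
treated as unimodal and requires a manual threshold.

Frame t lives at time t/fps with frame 0 at t = 0. Cycle windows are
half-open `[start, end)` so every frame belongs to exactly one window. The
nominal grid (delay 10 s, 2 s on, 1 s off, 400 cycles by default — i.e.
20 minutes of stimulation *after* the delay, which is what makes the last
ten cycles 391–400) is shifted onto the data by the measured lag between
nominal and decoded first onset, because acquisition starts asynchronously
with the stimulus program; a lag exceeding one cycle is treated as a
protocol/video mismatch. Lag compensation can be disabled.

## Normalization and cycle metrics

Traces are divided by the mean perimeter over the 2 s window immediately
before the first decoded onset — the window *mean*, not per-frame values,
so the baseline-window mean of every normalized trace is exactly 1. The
per-cycle rest value averages the trailing half of the preceding
off-window (configurable fraction; the animal needs the early off-phase to
relax, and no authoritative per-cycle "rest" definition exists, so the
default is documented rather than asserted). Maximum contraction is the
*minimum* normalized perimeter in the on-window, making amplitudes positive
for contracting animals. Fatigue compares mean amplitude of the first k
vs last k complete cycles (k = 3 by default). Group comparison is an
equal-variance two-sided Student's t-test (Welch behind a flag), with
box-plot summaries (mean, median, quartiles, 10–90 % whiskers) computed
per larva — one amplitude summary per animal, never pooled across animals.

Degenerate statistics are pinned: identical zero-variance groups give
t = 0, p = 1; zero-variance groups with different means report p at the
smallest positive float rather than failing.

## Mitochondrial content

Content = (bouton − background) mean in the mitochondrial channel divided
by the same in the cytosolic channel, after average-intensity z-projection.
Bouton ROIs are pooled as a pixel union by default (per-ROI-then-average
behind a flag; the field's own descriptions are ambiguous between the two).
Polygon ROIs rasterize by pixel-center inclusion with boundary centers
excluded (strict interior, via shapely); ellipse ROIs by the center-point
ellipse test. Negative (sub-background) signals are reported and flagged,
not clipped. Knockdown efficiency across terminal groups is
`100·(1 − mean(test)/mean(control))`. Aggregate avoidance is the user's
job at ROI-placement time.

## Phantoms

`phantom.render_phantom` draws a dark, axis-aligned ellipse (defaults:
semi-axes 30 × 9 px in a 120 × 160 frame, body 60 on background 180 with a
40-gray-level linear shade) whose semi-major axis relaxes exponentially
(default τ = 0.2 s) toward `a₀(1 − f)` during light-on and back during
light-off, plus an indicator dot drawn at exactly the on/off intensity and
optional additive Gaussian noise clipped to the bit depth (8-bit default).
Perimeter truth is Ramanujan's second approximation of the instantaneous
axes — its error is negligible against pixel-level tolerances. One seeded
generator drives all randomness; identical spec + seed is bit-identical.

What the phantom deliberately does **not** emulate: peristaltic waves,
bending/rearing postures, shadows, reflections, or multiple animals.
Passing phantom tests therefore demonstrates that the *pipeline* recovers
programmed geometry and timing under controlled degradation (noise, drift),
not that segmentation parameters transfer to any particular recording —
those must still be tuned per setup.

`render_bouton_pair` builds registered two-channel stacks of disk boutons
at programmed above-background levels, so the true content ratio is known
by construction. `synthesize_perimeter_trace` is a trace-level phantom
(per-cycle amplitudes → perimeter time series) for exercising the
normalization/metric/statistics stages at population scale, where
rendering and segmenting video per larva would add nothing but runtime.

## Validation conditions

The statistically flavored checks run at fixed, pre-chosen conditions:

* LED decoding: 20 seeded phantoms at noise sd = 10 % of the plateau
  separation; required ≥ 99 % frame accuracy (measured: 100 %).
* Amplitude recovery: 70 s phantom (20 cycles) at 10 fps, contraction 0.2,
  τ = 0.15 s; tolerance 10 % noiseless, 15 % at noise sd 5.
* Fatigue-detection power: N = 10 steady vs N = 9 declining larvae
  (30 % linear amplitude decline), 50 cycles per trial as a scaled-down
  protocol, per-larva baseline amplitude ~ N(0.20, 0.03), per-cycle jitter
  sd 0.01, frame noise 0.5 % of rest perimeter; p < 0.05 required in
  ≥ 90 of 100 seeded replicates.
* Knockdown recovery: 12 terminals/group, test level 0.13 × control;
  required 87 % ± 2 (noiseless) / ± 5 (noisy).

## Known limitations

* Bit-for-bit parity with ImageJ's Subtract Background (sliding-paraboloid
  refinement, its particular shrink heuristics) and with WrmTrck's
  unpublished perimeter/linking conventions is out of scope; accuracy is
  asserted against analytic shapes and ground truth instead.
* Single-animal only; a second larva entering frame will be rejected by the
  jump gate at best.
* The per-cycle rest definition and the per-frame vs frozen threshold
  choice are conventions with knobs, not recoverable facts; results should
  cite the settings used (the run log records them).
* AVI I/O requires an imageio video backend; frame directories and TIFF
  stacks are the dependency-free containers.
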