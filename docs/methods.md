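# Methods

## Problem and signal model

A radiometric long-wave infrared camera (nominally 384×288 px at 8.66
frames/s, ≈ 0.02 cm² per pixel) looks straight down on an arena during a
two-stage social test: a habituation phase in the empty arena, a ~30 s gap
while stimuli are introduced (excluded from all analysis), and a stimulus
trial. Urine and fecal deposits are emitted at body temperature, appear as
warm blobs on the cooler floor, cool over tens of seconds (large urine
pools over minutes) and settle slightly below the dry-floor temperature
because of evaporative cooling. The mouse itself is a large, persistently
warm blob; reflections and the stimulus animals are warm but do not cool.
The pipeline exploits exactly these contrasts.

## Radiometric calibration

Two sensor effects are removed before detection. Fixed-pattern
non-uniformity is estimated from frames of a uniform surface: the frames
are averaged and the average's own mean subtracted, giving a zero-mean
offset image that is subtracted from every frame. Slow drift of the
apparent temperature is cancelled against a constant blackbody (setpoint
37 °C) in the field of view: after NUC subtraction, the offset
`mean(frame[blackbody]) − 37` is subtracted. The acquisition protocol does
not fix whether the blackbody offset should be applied per frame or per
session; it is applied **per frame** by default (`per_frame=True`), because
cancelling drift is the stated purpose of the blackbody, and a session-wide
offset is available as an option. Calibration preserves the input floating
dtype; with float64 input, re-applying a null calibration to an already
calibrated video changes nothing beyond 1e−9.

## Preliminary hot-blob detection

All second-valued windows are converted to frames with `round(s·fps)`,
except the background window (below). Habituation and trial are processed
independently so small arena shifts between stages are harmless; track
identities are per stage.

Per frame `F_i` (0-based within a stage):

* **Mouse mask `M_i`** — `F_i − B_{i−1}` is grey-dilated with an exact
  Euclidean disk of radius 2 px and thresholded at 1 °C (strictly). The
  8-connected component with the largest floor overlap is the mouse; ties
  (including the all-zero-overlap case) go to the component whose first
  pixel comes earliest in row-major scan order. No warm pixels ⇒ empty
  mask. The 1 °C mouse threshold is deliberately lower than the blob
  threshold so deposits are not swallowed by darker parts of the animal.
* **Inpainted frame `N_i`** — mouse pixels keep `N_{i−1}`, all others take
  `F_i`; `N_{j<0} = B_0`.
* **Background `B_i`** — per-pixel minimum of `N_j` for
  `j ∈ [i−(5r−1), i−4r]` with `r = round(fps)`: one second's worth of
  frames ending 4 s back ([i−44, i−36] at 8.66 fps, 9 frames). This frame
  rule — rather than `round(s·fps)` endpoints — is used because it
  reproduces the nominal-rate window exactly. `B_0` is the per-pixel
  minimum over the first 20 s, assuming the mouse moves enough for every
  pixel to show floor at least once.
* **Difference `D_i = F_i − max(T, B_i)`** with `T` the **lower median**
  (even counts take the smaller middle value) of `B_i` over floor pixels
  outside `M_i ∪ M_{i−1}`. Using `T` keeps sensitivity uniform over floor
  regions darkened by old, cooled urine. A mouse covering the entire floor
  is an error (no eligible pixels).
* **Cooldown `CD_i`** — `F_i` minus the per-pixel minimum over the next
  40 s, truncated at the video end. Implemented with a sliding forward
  minimum (`scipy.ndimage.minimum_filter1d`), bit-identical to the naive
  per-frame minimum.
* **Hot-blob mask** — `D_i > ΔT_threshold` (default 1.6 °C) ∧ outside
  `M_i ∪ M_{i−1}` ∧ `CD_i > 1.1 °C` ∧ `CD_i > 0.5·D_i`; every inequality
  strict. `M_{i−1}` is excluded as well because the sensor's response time
  leaves just-vacated mouse pixels slightly warm. The cooldown is required
  to be at least *half* the excess, not all of it, because very large urine
  pools have not finished cooling within the 40 s horizon.
* **Blob refinement** — morphological closing with an exact disk of radius
  4 px (computed on a padded array, so it equals closing on an infinite
  background) merges nearby droplets; 8-connected blobs are discarded if
  any pixel leaves the floor mask (including closing spill-over), if they
  are 8-adjacent to `M_i ∪ M_{i−1}`, or if their size is < 2 or > 900 px.
* **Association** — a blob merges into the oldest existing track whose
  union mask it intersects and whose last detection is ≤ 30 s old
  (inclusive); otherwise it starts a new track. Tracks detected in ≥ 2
  frames are emitted; the reported frame is the one with maximal blob peak
  intensity in `D` (earliest on ties), the representative pixel the argmax
  of `D` in that frame's blob (row-major first on ties). The reported area
  is the union mask (the per-frame mask is a documented alternative; the
  union is robust to partial occlusion).

Intensity means the background-compensated difference `D`, not raw
temperature, so the selection is insensitive to floor gradients.

## Patch-sequence classifier

Anchored at a detection's representative pixel and selected frame, the
input is 78 patches of 65×65 px from frames `i + 8k`, `k ∈ [−12..65]`
(−11.1 s … +60.1 s at 8.66 fps; the frame formula is authoritative over the
rounded seconds). The long forward window captures cooldown, feces
displacement and urine smearing; the backward window covers depositions
briefly occluded by the mouse. Temperatures map linearly 10 °C → 0,
40 °C → 255 with clipping; missing frames *and* out-of-image pixels pad
with uniform 22 °C (grey 102.0). Triples of consecutive patches form 26
three-channel tokens in temporal order.

The classifier is a NumPy implementation of a single-query cross-attention
architecture:

* **Backbone ("tiny")** — each 65×65×3 token is block-mean pooled 5× to
  13×13×3, flattened (507 values, scaled to [0, 1]) and projected by a
  trainable affine map + ReLU to the joint dimension (256). Inputs are
  standardised with a per-feature mean and one global standard deviation
  fitted on the training set and stored in the model; a single global scale
  (rather than per-feature) keeps noise-only dimensions from being
  amplified.
* **Position/time code** — sinusoidal encodings (128 dims per axis, the
  same functional form for t as for x and y) of the anchor coordinates and
  the token index, each normalised to [0, 2π] over the nominal frame size
  / token count, concatenated to 384 and affinely mapped to 256, then added
  to the token embedding. The affine map is zero-initialised so training
  starts content-only; with unnormalised coordinates the high-frequency
  sinusoids form an interpolation basis that lets small models memorise
  training positions, which normalisation removes.
* **Head** — one learned query attends over the 26 tokens
  (`softmax(h·q/√d)` weights), and a linear layer maps the pooled vector to
  urine / feces / background scores (softmax; scores sum to 1).

Training uses class-balanced cross-entropy and Adam with analytic
gradients (verified against finite differences), two learning-rate groups
(backbone vs the rest) and a step drop after a configurable epoch. The
two-round reference schedule (230 epochs with a ×10 drop after 200, then 50
epochs with a drop after 40; backbone 1e−5, rest 1e−4) is provided as
`ROUND1`/`ROUND2`; the desk-scale default is a single round (tiny backbone,
lr 1e−3, minibatch 16). Training is exactly reproducible from its seed.

Training sets contain: a positive per manual tag; 40 random negatives per
video (20 per stage), resampled (budget 1 000 tries) while within 25 px
**and** −10 s ≤ t_d − t_m ≤ 30 s of any tag; and hard negatives — heuristic
detections failing that closeness test. Augmentation shifts positive
anchors in time by a uniform draw from [−3 s, +6 s] (once per augmented
copy, not per epoch), shifts all anchors spatially by integers in {−2..2}²,
and applies random horizontal/vertical flips and 90° rotations; labels are
preserved. Flips/rotations act on extracted patches; anchor shifts act
before extraction (on already-extracted patches a shift is applied by
translation with edge replication).

## Accuracy measurement

A tag is correctly detected if a same-label detection lies within 20 px
(≈ 2.9 cm) and 15 s — both inclusive ("up to"). All unmatched same-label
detections in that window are absorbed by the tag (never false alarms). If
only wrong-label detections lie in the window, the closest one — smallest
spatial distance, ties by smallest |Δt|, then lowest detection id — is the
misclassification; the remaining window detections are *not* consumed, so
they can still match later tags, and count as false alarms only if nothing
claims them. Ground truth is processed greedily in order of occurrence
(time, then x, y, label) and each detection is matched at most once.

The confusion matrix has ground-truth rows (urine, feces, BG, Miss) and
predicted columns (urine, feces, BG): detections classified background that
sit in a tag's window land in that row's BG column; the Miss row counts
tags with no detection in the window, indexed by the tag's own class; the
BG row counts false alarms by predicted label. Per class,
`precision = TP/(TP+FP)`, `recall = TP/(TP+FN)` with FP = false alarms +
cross-class misclassifications predicted as the class and FN = misses +
misclassifications of the class's tags; zero denominators score 0, and
`mean F1 = (F1_urine + F1_feces)/2`. Stratified reports (stage windows,
test label, subject sex, three equal-width floor divisions along the long
axis) mark a class with no ground truth in a stratum as undefined (None)
rather than 0, and the mean F1 is undefined if either class is.

## Deposition dynamics

Minute bins are half-open `[60k, 60(k+1))` seconds from stage start. The
comparison windows are habituation minutes 1–4 (`[0, 240)` s) and 11–14
(`[600, 840)` s), trial minute 1 (`[0, 60)`) and minutes 2–4
(`[60, 240)`). An optional exclusion flag drops events in the final minute
of each stage (habituation `[840, 900)`, trial `[240, 300)`) — the
classifier needs about a minute of subsequent video, so accuracy drops
there — which leaves the standard windows unchanged. A subject is *active*
for a label if it has at least one such event in the session. Sides are
assigned by the midline perpendicular to the floor bounding box's long
axis (chambers sit at opposite corners); midline points belong to the
first-listed ("left") side. Areas are the detection-time union-mask areas.
Statistical testing is deliberately out of scope; summaries are exported
as CSV for external tools.

## Synthetic sessions

The generator renders, per frame: a static floor field (mean 25 °C,
smooth spatial texture σ = 0.3 °C) inside the annotated floor polygon,
cooler walls (22 °C), a blackbody patch at 37 °C; each deposit as a disk
adding `peak·e^{−a/τ} − dark·(1 − e^{−a/τ})` (age `a`, asymptote 0.5 °C
*below* floor) with a mild radial profile (centre 15 % warmer than the rim)
so the representative pixel is well defined; a soft-edged 35 °C mouse disk
on a reflecting random walk (step σ 1.8 px/frame); then global sinusoidal
drift (±0.3 °C), a fixed zero-mean non-uniformity pattern (σ 0.3 °C) and
iid Gaussian noise. One seeded generator drives everything; a fixed seed
reproduces the saved container byte-identically.

Preset study conditions: **easy** — 160×120 px frames, 120 s habituation +
120 s trial, 5 urine (radius 3–5 px, τ 35–55 s) + 5 feces (radius
1.2–2 px, τ 30–60 s) per session at 9–11 °C peak excess, deposit times
25–75 s into each stage (so ≥ 45 s of video follows each deposit,
mirroring the last-minute exclusion rationale), pairwise separation
≥ 30 px, noise σ = 0.05 °C, and the mouse path kept ≥ 20 px clear of
deposit sites; **occlusion** — the mouse parks on deposit sites around
deposition time instead; **dense** — 16 events including large slow urine
pools (radius 6–9 px, τ up to 240 s), with site avoidance only in a window
around each deposition. Event positions are drawn on a randomly chosen,
jittered grid, which guarantees the minimum separation. The frame size and
stage durations are scaled-down study conditions chosen so that full
sessions remain cheap to render while every algorithmic window (20 s
background init, 5 s background lag, 40 s cooldown horizon, 30 s
association gap, ±60 s classifier context) fits comfortably inside a stage.

What the generator does **not** emulate — and what passing tests therefore
do not show about real recordings: fur/posture structure and the tail
(real mouse masks are irregular; the tail causes dark-rim artefacts),
urine smearing and feces displacement by the mouse, stimulus animals
poking through chamber meshes, reflections from walls, flicker or vignette
beyond a global drift, and multi-animal scenes. Synthetic deposits are
clean disks with a single exponential time constant, so classification on
these sessions is substantially easier than on real video; synthetic
scores certify the machinery (detection, matching, training, scoring),
not field accuracy.

## Numerical and design notes

* All coordinates are 0-based, x = column, y = row, origin top-left; frame
  intervals are closed `[first, last]`; pixel (x, y) has its centre at
  (x, y) for polygon rasterisation (strict interior, even-odd rule — both
  rules agree on the simple polygons required).
* Detection runs in float32 (the container quantises to 0.01 °C anyway);
  calibration preserves the input dtype.
* Deterministic tie-breaks everywhere: scan-order component selection,
  earliest frame on equal peaks, row-major argmax pixel, oldest track on
  multi-track overlap, smallest id in matching.
* Degenerate inputs raise: empty uniform-frame lists, mismatched shapes,
  empty blackbody masks, polygons with < 3 vertices or self-intersections,
  videos shorter than the background-init window, a mouse covering the
  whole floor, training sets missing a class, non-finite losses.
* Whether a detection may satisfy two tags simultaneously was open; each
  detection is consumed by the first (earliest) tag that claims it.
* Problem sizes in the test suite and acceptance script: the classifier is
  trained on 20 (tests) or 12 (acceptance script) simulated sessions with
  two augmented copies per positive (~70 examples per session) and scored
  on 5 / 4 held-out sessions; detector-vs-reference equivalence uses
  twenty 24×24 px, 300-frame random clips. These sizes are the package's
  own desk-scale choices and can be raised freely.

## Known limitations

* The 50-layer residual reference backbone and transfer-learning
  initialisation are not implemented; the tiny pooled-patch backbone is
  the supported configuration, sized for desk-scale data. The attention
  stage is a single cross-attention layer with one query, not a full
  encoder–decoder stack.
* Deposits occluded by a mouse that lingers on them can be missed — by
  design the detector needs the blob visible while still warm (the
  `occlusion` preset reproduces this failure mode).
* Repeated urination at one spot within the association window merges into
  a single detection; displaced feces are re-detected as new events rather
  than tracked.
* The matcher's greedy tag ordering and the midline side rule are
  documented conventions, not uniquely determined by the protocol.
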