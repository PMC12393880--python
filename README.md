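# thermark

Automatic detection and classification of mouse urine and fecal depositions
from overhead radiometric thermal video.

Scent marking — depositing urine and feces — is a core channel of rodent
social communication, but the classical void spot assay (filter paper
inspected after the experiment) has no temporal resolution and is corrupted
by urine smearing. An overhead long-wave infrared camera sees each deposit
the moment it is made: it appears at body temperature on a cooler arena
floor, then cools within tens of seconds (large urine pools take minutes)
and ends up slightly *darker* than the dry floor. `thermark` turns that
phenomenology into a two-stage pipeline for standard two-stage social tests
(a habituation phase in an empty arena followed by a stimulus trial):

1. **Preliminary hot-blob detection.** For each frame `F_i` a background
   `B_i` is maintained as the per-pixel minimum of mouse-inpainted frames
   from roughly 5 to 4 seconds earlier (`B_0` is the minimum over the first
   20 s). The mouse mask is the warm connected component with the largest
   arena-floor overlap of `dilate(F_i − B_{i−1}) > 1 °C`. Candidate pixels
   satisfy, with `T` the floor median of `B_i`,

       D_i = F_i − max(T, B_i) > ΔT_threshold   (default 1.6 °C)
       CD_i = F_i − min of the next 40 s        CD_i > 1.1 °C,  CD_i > 0.5·D_i

   i.e. they are warmer than the background *and* cool down afterwards.
   Blobs are cleaned by morphological closing (disk radius 4), filtered by
   size (2–900 px, ≈ 0.02 cm² per pixel) and contact with the mouse, and
   associated over time (mask overlap within 30 s). Tracks seen in at least
   two frames become detections, reported at the frame and pixel of maximal
   `D`.
2. **Patch-sequence classification.** Each detection is described by 78
   grayscale 65×65 patches from frames `i + 8k`, `k ∈ [−12..65]`
   (≈ −11 s … +60 s), normalised by mapping 10 °C → 0 and 40 °C → 255 and
   padded with 22 °C where the video ends. Patch triples form 26
   three-channel tokens; a trainable backbone embeds each token, a
   sinusoidal (x, y, t) encoding (128 dims per axis, affinely mapped
   384 → 256) is added, and a single learned query attends over the tokens
   to produce urine / feces / background scores. Training sets combine the
   manual tags, 40 random floor negatives per video and "hard negatives"
   (heuristic detections matching no tag), with flip/rotation/shift
   augmentation.

Evaluation follows the matched-tolerance protocol: a tag counts as detected
if a same-label detection lies within 20 px and 15 s; absorbed duplicates
are not false alarms; otherwise the closest wrong-label detection is the
misclassification. Reports include the confusion matrix with Miss row and
BG column, per-class precision/recall/F1 and mean F1
`(F1_urine + F1_feces)/2`, plus deposition-dynamics summaries (per-minute
rates and areas, stage windows, percent active subjects, stimulus-side
attribution).

A seeded synthetic-session generator (`thermark.thermsim`) renders the whole
phenomenology — wandering warm mouse, deposits with exponential cooldown to
a below-floor asymptote, fixed-pattern non-uniformity, sensor drift
referenced to a 37 °C blackbody, Gaussian noise — with exact ground truth,
and is the test substrate for every stage.

## Worked example

```python
import thermark as tm

cfg = tm.config_from_preset("easy", seed=1)     # 2-min stages, 5 urine + 5 feces
sim = tm.render_session(cfg)
video = tm.apply_calibration(sim.video, sim.calibration)
detections = tm.run_preliminary_detection(video, sim.annotation)
print(f"{len(detections)} preliminary detections, "
      f"{len(sim.gt_events)} scheduled deposits")
for d in detections[:3]:
    print(f"  {d.stage:12s} t={d.time_s:6.1f} s  ({d.x:3d},{d.y:3d})  "
          f"area {d.area_cm2:.2f} cm^2")
```

prints

```
10 preliminary detections, 10 scheduled deposits
  habituation  t=  39.5 s  ( 21, 59)  area 0.18 cm^2
  habituation  t=  43.3 s  (144, 14)  area 1.38 cm^2
  habituation  t=  60.2 s  (147, 57)  area 0.10 cm^2
```

— every scheduled deposit is recovered (the 0.18/0.10 cm² blobs are feces,
the 1.38 cm² blob a urine pool). Scoring label-matched detections against
the ground truth with the tolerance matcher gives

```
urine P/R/F1 = 1.00/1.00/1.00
feces P/R/F1 = 1.00/1.00/1.00
mean F1 = 1.00
```

The same pipeline is available from the shell:

```sh
thermark simulate --preset easy --seed 7 --out sessions/s7
thermark detect  sessions/s7
thermark train   sessions/s7 --out model.npz --seed 0
thermark classify sessions/s7 --model model.npz
thermark evaluate sessions/s7        # writes report.json
thermark summarize sessions/s7       # stage windows, per-minute series, sides
```

Each command writes a manifest echoing its configuration and seeds; reruns
with the same inputs are byte-identical.

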