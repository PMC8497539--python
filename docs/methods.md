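# Methods

This note documents the models, parameter choices and numerical decisions
behind `swallowtrack`, and what its synthetic benchmarks do and do not
demonstrate about real recordings.

## Measurement model

The observable is a front-view video of the lower neck bearing nine circular
stickers (diameter 5 mm) in a 3×3 grid around the incision line: rows H
(1 cm above), M (on) and L (1 cm below the wound), columns 1–3 left to
right. Swallowing raises the larynx and drags the overlying skin vertically;
adhesions reduce that travel. Horizontal marker motion is small and ignored
throughout — the endpoint is purely vertical.

Per session the pipeline computes one scalar, the **session distance**: the
median over the three guided swallows of the excursion (max − min) of the
mean vertical marker trajectory, in millimeters. The median absorbs a single
corrupted swallow; max − min makes the result independent of the y-axis sign
convention (origin top-left, y down, pixel centers at integer coordinates).

### Averaging recognized markers

Markers intermittently fail to detect (occlusion, lighting). The per-frame
trajectory is the mean over *recognized* markers only; frames with no
recognized marker are gaps filled by linear interpolation (end gaps held).
One subtlety: the nine markers sit at different image heights, so a mean of
raw coordinates jumps by (row offset)/(n recognized) whenever a marker drops
out — an artifact of dropout, not motion, that can exceed 1 mm. What the
endpoint intends to average is each marker's *motion*, so by default every
track is first referenced to its own session rest position (the median of
its recognized y; the markers rest far more than they swallow, making the
median a stable rest estimate). The mean rest position is added back so the
trajectory stays in image coordinates; without dropout this is exactly the
plain coordinate mean shifted by a constant, and excursions are unchanged.
`mean_trajectory(..., center=False)` restores literal coordinate averaging.
An alternative ordering — per-marker excursions first, averaged after — is
available via `excursion_order="excursion_first"`; on clean synchronous
motion the two agree, and average-first is the default because it composes
naturally with the dropout rule.

### Calibration

mm/px = 5 mm / (mean first-frame pixel diameter over recognized markers).
The mean over up to nine markers damps single-blob segmentation error.
Thresholding an anti-aliased disk biases the apparent diameter by a fraction
of a pixel, giving a ~0.5–1 % scale bias; at 6 mm excursions this is
≤ 0.06 mm and is the dominant residual in the recovery benchmarks.

### Swallow segmentation

Recordings follow a fixed voice guide, so the default is **schedule mode**:
windows 8–14 s, 18–24 s, 28–34 s of the 36 s protocol (generous 6 s windows
centered on the three swallows at onsets 8/18/28 s, leaving a quiet
baseline). An **auto mode** instead takes the three highest-prominence
pulses of the mean trajectory (prominence ≥ 10 % of the signal span),
widened by a configurable half-width and truncated at midpoints; it refuses
to guess when fewer than three pulses exist and directs the user to schedule
mode. One configuration object carries the schedule into both the simulator
and the analyzer so the two can never drift apart.

## Detection

- **HSV thresholds** (configurable): blue h ∈ [200°, 260°], green
  [90°, 150°], yellow [45°, 70°], orange [15°, 40°]; s ≥ 0.4, v ≥ 0.3. The
  four bands are pairwise disjoint, and the saturation floor separates the
  stickers from skin, whose hue overlaps orange but whose saturation is
  lower. Brightness changes scale v and leave h/s nearly fixed, which is
  what makes the gate tolerate illumination drift.
- **Connected components**: 8-connected, minimum area 20 px (rejects noise
  speckle; a 25 px-diameter marker has area ≈ 490 px). Centroids are
  intensity-unweighted; diameters are area-equivalent.
- **Grid labeling** uses geometry only — the protocol does not fix which
  color occupies which position, so color identity cannot label markers.
  Nine blobs: sort by y, split into three rows, order rows by x (ties by
  area). Fewer: Hungarian assignment against the previous frame's labeled
  positions (first frame: a 3×3 lattice spanning the blob extent). More than
  nine: keep the nine largest and warn.
- **Jump rejection**: a label whose centroid would move more than 3 marker
  diameters from its last recognized position in one frame is discarded for
  that frame — momentary top/bottom flips and flicker misdetections produce
  exactly such jumps.

## Synthetic sessions

The generator emulates the recording protocol: default 36 s at 30 fps,
three raised-cosine swallow pulses (peak 6 mm, 4 s duration, onsets
8/18/28 s — evenly spaced with a quiet lead-in), 5 mm markers on a 3×3 grid
(rows 10 mm apart matching the 1 cm placement; columns 15 mm apart, a free
protocol parameter), a fixed repeating color assignment, and a default scale
of 0.1 mm/px (a 5 mm sticker spans 50 px). Disks are anti-aliased
(coverage-weighted alpha compositing) over a skin-tone background whose
gradient and low-frequency texture modulate *brightness* multiplicatively —
shading changes value, not saturation, as shading on real skin largely does.
Optional degradations: per-frame additive Gaussian pixel noise; sinusoidal
illumination drift over the session; per-marker-per-frame Bernoulli dropout
(a dropped marker is simply not rendered); per-row excursion gains in [0, 1]
emulating an adhesion-like restriction; optional x-jitter. All randomness
flows from one seed; identical specs render bit-identical sessions.

Ground truth carries the exact trajectories, the per-swallow excursions of
the mean trajectory and their median. With row gains g and peak A, a
marker's true excursion is g·A and the mean-trajectory excursion is mean(g)·A.

**What the generator does not model**: real anatomy and texture, specular
highlights, motion blur, rolling shutter, perspective and out-of-plane neck
motion, correlated occlusions (chin, collar), or inter-swallow variability
in waveform shape. Passing the recovery benchmarks therefore demonstrates
the correctness and numerical accuracy of the pipeline on protocol-faithful
inputs, not detection robustness on clinical video.

Trial simulation draws each subject's baseline distance and per-follow-up
changes from per-arm normal distributions (defaults: the reported per-arm
summaries — treated 3.92 ± 1.19 mm baseline with changes 2.96 ± 2.1 /
1.8 ± 1.52 / 1.45 ± 1.66 mm; control 4.1 ± 1.38 with 2.04 ± 1.85 /
1.1 ± 1.55 / 0.58 ± 1.5 mm), floored at zero; covariates sample the
eligible population (age 20–65, ~36 % male, height ~N(160, 7) cm).

## Trial statistics

- **Baseline subtraction** per subject; missing baselines are logged and
  excluded from change endpoints; negative changes are legitimate.
- **Outlier screening** per arm on one endpoint, either an iterative
  two-sided Grubbs test at α = 0.05 (critical value
  ((n−1)/√n)·√(t²/(n−2+t²)), t = t₁₋α/(2n),n−2) or a fixed-count mode
  removing the k most extreme deviations (k = 5 mirrors the analyzed-cohort
  bookkeeping of 49 → 44 per arm). The significance criterion behind the
  original screening is not fully specified, hence both modes; the default
  screening endpoint is the 2-week change (the largest, hence most
  outlier-prone, endpoint), configurable.
- **t-tests**: Welch by default (robust to unequal variances), pooled
  available; both reproduce the reported significances. Summary-statistic
  input is supported and is exactly equivalent to raw input realizing the
  same summaries (pooled). Two constant equal samples give p = 1 by
  convention, logged.
- **Mann–Whitney U** (subgroups): exact enumeration when combined n ≤ 20
  with no ties, otherwise normal approximation with tie and continuity
  corrections; U uses mid-ranks.
- **Subgroups**: sex M/F, age < 50 vs ≥ 50 years, height < 160 vs ≥ 160 cm
  (boundaries configurable; subjects exactly at a boundary go to the upper
  band). Empty strata are reported not-testable rather than aborting.
- **Multiplicity**: per-endpoint p-values are unadjusted by default,
  matching the reporting convention; a Holm flag is available.

## Benchmark problem sizes

Benchmarks run at a reduced recording format — 480×360 px, 10 fps, 12 s
sessions with swallows at onsets 2/5.5/9 s (2 s each, peaks on exact frame
times), scale 0.2 mm/px — which exercises every stage identically to the
full format at a fraction of the rendering cost. The recovery sweep uses 50
sessions with peaks uniform in 2–10 mm, dropout up to 10 %, noise
σ = 0.02 and 10 % illumination drift, and achieves a mean absolute
session-distance error of ~0.05 mm (bound 0.2 mm); clean sessions track
with ~0.02 px RMS centroid error. Type-I calibration uses 200 null-effect
trials of 44 per arm.

## Known limitations

- Orange stickers and strongly flushed or deeply pigmented skin can
  approach each other in HSV; real deployments should verify the saturation
  margin on first-frame histograms, or recolor the orange stickers.
- Grid labeling assumes the camera is roughly upright; a rotated camera
  would scramble the row partition.
- The scale is calibrated once from the first frame; subject-camera
  distance changes within a session are not corrected.
- Auto swallow segmentation needs visible pulses; very restricted swallows
  (excursion near noise level) require schedule mode.
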