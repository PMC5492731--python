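# Methods

`henmon` implements an infrared presence sensor for laying hens in a closed
room of a free-range housing system. The practical problem is sanitary:
ozone treatments of the housing area are toxic, so equipment must only run
when the room is verifiably empty. The sensor decides, once per short
monitoring slot, whether at least one hen is present in the thermal
camera's field of view.

## Detection model

A ceiling-mounted thermal camera delivers 8-bit grey frames (nominally
320 × 240) in which grey level is linearly related to surface temperature.
Hens are warmer than the floor, so detection reduces to finding hen-shaped
warm regions against a cooler background. The per-frame chain is:

1. **Histogram / floor estimate.** The floor dominates the frame, so the
   grey-level histogram peaks at the floor temperature. The floor estimate
   is the histogram mode by default (`floor_method="mode"`), with a 10%
   two-sided trimmed mean as an alternative (`"trimmed-mean"`). For the
   idealized near-normal background the two coincide; the mode is more
   robust when a hen occupies a large image fraction. Working relative to
   this per-frame estimate is what absorbs the camera's absolute
   temperature error (±2 °C class): a constant offset moves floor and hen
   together and cancels out.
2. **Background Color Threshold (BCT).** A configured temperature shift
   Δt > 0 (default 1 °C) is added to the floor estimate and converted back
   to a grey level. Pixels *strictly above* the BCT are foreground.
   Strictness is a declared convention so decisions are bit-reproducible.
3. **Particle filter.** Morphological opening (disc, radius 1 by default)
   followed by removal of 8-connected components below `min_particle_area`
   (30 px default) suppresses noise specks and small thermal residues
   (foot imprints, etc.). The filter is idempotent and never adds area.
4. **Colored Pixels (CP).** The count of surviving foreground pixels.
5. **Pattern recognition.** Normalized cross-correlation (NCC) between the
   filtered binary mask (values treated as 0/1 intensities) and a binary
   hen template, maximized over placements and a rotation grid. The score

       R(i,j) = Σ[(t − t̄)(p − p̄_ij)] / (‖t − t̄‖ · ‖p − p̄_ij‖)

   lies in [−1, 1] and is invariant to positive affine intensity maps.
6. **Decision.** HD (hens detected) = 1 if the best NCC score reaches the
   acceptance threshold, else if CP strictly exceeds the Colored Pixels
   Threshold (CPT, default 1736 px, proportional to one hen's visible
   thermal imprint), else 0. The fallback catches hens whose pose or
   truncation at the frame edge defeats the template.

A monitoring run groups time-ordered frames into fixed slots (2 s default,
one frame per slot in the default configuration, any-frame-positive
aggregation when a slot holds several frames) and appends one TSV log
record per slot: slot start/end timestamps, HD, CP, BCT, shift, template
id, best NCC score and warnings.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| calibration | 0 °C at level 0, 0.1 °C/level | — | covers 0–25.5 °C, spanning the 5–13 °C ambient range with headroom for hen surfaces; makes a 1 °C shift exactly 10 grey levels |
| `shift` | 1.0 | °C | the sweep over 1/2/3 °C favours 1 °C: nearly the whole hen body stays visible |
| template | ellipse 135 × 63 | px | calibrated body geometry at 1 °C shift; triangle 35 × 16 and 18 × 12 are the head-scale templates for 2 and 3 °C |
| `ncc_threshold` | 0.5 | — | acceptance score; a planted full hen scores ≳0.9, small round artifacts ≲0.15, so 0.5 separates them with margin |
| `cpt` | 1736 | px | about a quarter of a full hen imprint (≈6680 px); the most restrictive visible-area case |
| `min_particle_area` / `opening_radius` | 30 / 1 | px | smallest hen fragment worth keeping vs. noise specks |
| rotation grid | 0–165° step 15° (ellipse); 0–345° (triangle) | deg | ellipse has 180° symmetry; 15° is fine enough that the NCC peak degrades only a few percent between grid points |
| `slot_seconds` | 2.0 | s | one decision per slot; a single frame suffices |

Numerical conventions: NCC windows with (numerically) constant image
content score 0 rather than NaN; the raw correlation on integer inputs is
returned exactly (FFT results are rounded back to integers, safe because
all magnitudes are far below 2^53); template rotation uses nearest-
neighbour resampling so masks stay binary; NCC ties during the rotation
search resolve to the lowest angle, then the lowest (row, col). Small
images (≤128² px) take an exact direct-summation path; camera-size frames
take the FFT + integral-image path (identical to ~1e-7).

## Synthetic scene generator

No field imagery is distributable, so `henmon.simulate` renders the
operating scene: a floor at 8 °C (configurable over 5–13 °C) with i.i.d.
Gaussian pixel noise at the camera's 0.04 °C sensitivity; hens as rotated
filled ellipses (nominal 135 × 63 px, optional axis jitter) at a body
contrast Δt above the floor (sampled uniformly from 1–4 °C by default)
with a hotter head disc (+1 °C extra) near one end of the major axis; and
three nuisance classes: paired foot-imprint discs at +0.5 °C, an egg disc
(radius 8–12 px) at hen body temperature, and a warm floor patch at
+1.5 °C. Per-frame artifact probabilities default to 0.05 / 0.02 / 0.02 —
occasional nuisances rather than persistent clutter, so a long window sees
tens of artifact frames. Frame randomness derives from (seed, slot index),
so any slot renders bit-identically in isolation or in sequence.

The generator reproduces the qualitative shift regime that motivates the
template choices: with a body contrast between 1 and 3 °C (e.g. 2.5 °C),
the full body binarizes at a 1 °C shift while only the head disc survives
a 3 °C shift (measured head/body area ratio ≈ 0.05).

What the generator does **not** model: emissivity and reflection effects,
perspective distortion, fixed-pattern camera noise, partial occlusion,
deformable posture, or multi-hen interaction. Passing benchmarks on this
scene therefore demonstrate the correctness and internal consistency of
the processing chain under controlled contrast and noise — not field
accuracy on real animals, which depends on thermal contrasts and shape
variability the simulator idealizes.

## Evaluation

Slot decisions are tallied against per-slot ground truth into TP/FP/TN/FN
and summarized as sensitivity 100·TP/(FN+TP), specificity 100·TN/(FP+TN),
error rate 100·FP/(FP+TP), and accuracy 100·(TP+TN)/total. Values are
reported rounded half-up to one decimal; a metric with a zero denominator
is reported absent, never as zero.

## Design choices where the design was open

- **Floor statistic:** both mode and trimmed mean are exposed; neither is
  claimed to be the "true" original statistic.
- **Equivalent rectangle:** the oriented rectangle is the principal-axes
  extent of the component (a bounding measure), not the moments-equivalent
  rectangle; "long and short side" reads as an extent.
- **Matching domain:** the template is matched against the *binary*
  filtered mask, since pattern recognition follows binarization in the
  processing chain; full-overlap placements only.
- **Calibration feature switch:** ellipse axes are accumulated for shifts
  ≤ 1 °C, oriented-rectangle sides above, matching which body part remains
  visible; the largest particle per single-hen frame is taken as the hen.
- **Template rounding:** calibrated means round to the nearest integer
  pixel (134.8 → 135, 62.6 → 63).
- **Saturation:** a BCT clamped at 255 yields a warning record, not an
  error, so monitoring survives hot-floor frames.

## Problem sizes

The bundled benchmark uses a 1000-slot window at 50% occupancy (and a
second 1000-slot empty window for the false-alarm rate), 50-frame
calibration sets over three seeds, and 20-frame shift-regime checks —
sizes at which the stochastic metrics are stable to well under a
percentage point while the whole suite runs in a couple of minutes.

## Known limitations

- Single scalar floor temperature per frame; spatially varying backgrounds
  (sunlit patches) are out of scope.
- No scale compensation in matching: a hen much nearer or farther than the
  calibrated geometry lowers the NCC score and must be caught by the CP
  fallback.
- One detection suffices: the sensor reports presence, not a hen count or
  positions of multiple hens.
- The NCC acceptance threshold (0.5) and the 15° rotation step are this
  package's defaults, chosen by the separation argument above and exposed
  in the configuration.
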