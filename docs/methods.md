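# Methods

`earlyvision` asks a narrow, quantitative question: how much linearly
decodable category information do the *first* stages of visual processing
carry, and how quickly does it degrade under the nuisances a peripheral
detector must tolerate — changes of scale, orientation, position, and
background clutter?  The package answers it by fixing biologically
motivated encoders, training only a linear readout on top of them, and
measuring cross-validated classification of face-like versus non-face
stimuli.

## Encoders

Four fixed filter banks, all tiling a 340x340 grayscale canvas with four
spatial-frequency channels one octave apart (carrier wavelengths λ = 256,
128, 64, 32 px) at stride λ/2:

- **V1 simple**: oriented Gabor filters, 4 orientations (0° = vertical,
  45°, 90°, 135°) x 4 spatial phases (0°, 90°, 180°, 270°).  Envelope SD =
  0.4λ; support truncated to round(1.5λ).  Each output is half-rectified
  (max(0, ·)).  7,088 units: 144 + 144 + 1,024 + 5,776 across channels.
- **V1 complex**: energy-style pooling — the four rectified phase responses
  at each (position, λ, orientation) are summed, giving phase-invariant
  units.  1,772 units.
- **V1 linear RF**: the simple model without rectification.  Phases 180°
  and 270° are the exact negations of 0° and 90° and therefore redundant to
  a signed linear readout; they are dropped.  3,544 units.
- **LGN**: circularly symmetric difference-of-Gaussians filters, on- and
  off-center, with center SD = λ/12, surround SD = 5x center, surround gain
  0.2, center gain 1, same support as the matching V1 channel.  Rectified.
  886 units: 18 + 18 + 128 + 722.

Numerical conventions (the sources of these models are typically silent on
them):

- Kernels are mean-subtracted (zero DC; not applied to the DoG, which keeps
  its native 0.8 DC balance) and scaled to unit L2 norm; canvas luminance is
  mapped to [0, 1] before filtering.  Zero DC removes spurious responses to
  uniform backgrounds.
- A single global response gain of 4/√7088 scales the canvas before
  filtering.  The readout protocol fixes the learning rate, and one SGD
  step changes the logit by roughly lr·‖f‖²; with unit-L2 kernels alone
  ‖f‖ ~ √(unit count), the step is in the hundreds and training saturates
  and oscillates, while a gain of exactly 1/√7088 leaves steps too small to
  converge within a reduced-scale run.  The shipped gain puts per-step
  logit changes at order one for every bank; because it is shared and all
  encoder identities are homogeneous, no cross-bank identity is affected.
- The DoG center/surround Gaussians are normalized by their *discrete sum
  over the truncated support* ("integrated sensitivity" convention), so the
  on-kernel sums to exactly 1 − 0.2 = 0.8 before L2 scaling.  Normalizing
  by the continuous 2πσ² instead would lose ~14% of the surround mass to
  truncation and change the DC balance.
- The λ = 256 channel's support (384 px) exceeds the canvas.  The canvas is
  symmetrically zero-padded so a centered 3x3 grid at stride 128 exists —
  the only convention consistent with the published per-channel unit count
  (144 = 3x3x16).
- Raw responses are computed for phases {0°, 90°} only; phases 180°/270°
  follow from r(φ+180°) = −r(φ), and max(0, x) + max(0, −x) = |x| gives the
  complex units.  The expansion is checked against direct dot products with
  the full explicit kernel set at 1e-10 relative tolerance.  Banks can be
  built in float32 (`dtype=np.float32`); the packaged benchmark uses this
  for throughput, the default is float64.
- Higher-frequency channels (λ ≤ 16 px) are deliberately absent: with ±42 px
  position jitter they cannot carry reliable information and would only add
  noise to the readout.

## Stimuli

The reference image sets (frontal faces, web-collected objects, curated
scenes) are not distributable, so the package generates synthetic stand-ins
that reproduce the low-level statistics the encoders see:

- **Faces**: a high-fill superellipse foreground (taller than wide,
  exponent 4–8) containing two bilateral dark eye ellipses, a dark mouth
  bar, and smooth shading; elongation ~ N(1.60, 0.16) truncated to
  [1.15, 2.2].  Gender-task variants shift feature geometry (male-like:
  wider face, smaller eyes, heavier mouth, jaw shading; female-like: the
  reverse).
- **Non-faces**: unions of 3–6 random ellipses stretched to a tight
  bounding box, or (25% of draws) a single oval — mirroring the deliberate
  inclusion of oval shapes in the reference object set; elongation is a
  broad log-normal (median ≈ 2.3, clipped to [1, 6]).
- Foreground bounding boxes always have largest side 246 px, centered on a
  256x256 canvas with a binary alpha mask; alpha becomes fractional only
  after geometric interpolation.
- Per-image foreground luminance is affinely rescaled (iterated against the
  [0, 255] clip) to a drawn target mean (~103) and RMS contrast (~41.5, the
  unnormalized SD of foreground luminance).  Non-faces are generated ~15%
  dimmer and the set-level matching step (`match_luminance_sets`)
  multiplies them back up, reproducing the published brighten-by-15%
  adjustment; after matching, class means of luminance and contrast agree
  to better than 2%.
- A note on joint feasibility: with the largest side fixed at 246 px, a
  foreground of elongation e can fill at most 246·(246/e)/256² = 0.923/e of
  the canvas.  Published face means (fraction filled 0.56 at elongation
  1.66) sit exactly at that bound and are attainable only as means of a
  correlated joint distribution; the generator's high-fill superellipses
  land the face means near 0.55/1.61, inside the target windows.
- **Scenes**: horizon split + 1/f-spectrum texture + a few oriented bars,
  histogram-equalized to an approximately uniform luminance CDF.  Scene
  backgrounds are drawn from a fixed pre-generated library of 48 scenes per
  run (a finite curated scene set is reused across presentations in the
  reference protocol); the blurred variant halves contrast about each
  scene's mean and blurs with a 3 px SD Gaussian.

What the generator does *not* emulate: photorealistic texture, hair,
illumination direction, 3-D pose, the long-tailed shape diversity of real
object photographs, and any family resemblance between a face's identity
across images.  Passing benchmarks therefore demonstrate that the pipeline
reproduces the *structural* results (model orderings, nuisance robustness
trends, lesion redundancy) on stimuli with matched low-level statistics —
not the absolute percent-correct values reported for the real image sets.

## Presentation

Each presentation composes a fresh canvas: isotropic down-scaling by
u ~ U[scale_min, 1], then rotation by ρ ~ U[−rot_max, +rot_max] about the
256x256 center (bilinear, transparent fill; order chosen so rotation never
clips a pre-scaled image), then alpha compositing at the 340x340 canvas
center plus integer jitter uniform on [−42, +42] px per axis — exactly the
(340−256)/2 margin, so the foreground always lands inside.  Stimulus pixels
are stored premultiplied by alpha.  Eight background kinds: mid-gray (128),
image-mean gray, full-resolution 1/f ("pink") noise (mean 128, RMS 40),
4x4-px-block white/binary/image-sampled pixelated noise, high-contrast
scenes, and blurred scenes.

## Readout and training

A single linear unit (weights + bias) per model, trained with SGD
(learning rate 0.01, classical momentum 0.9, batch 64, shuffled) on the
binary cross-entropy-with-logits loss.  Weights start Kaiming-uniform
U(±1/√n) — the common linear-layer default for that initialization; the
√(6/n) variant would only rescale the first SGD steps — and the bias at 0.
Two protocols:

- **fixed**: 10 epochs, 1,500 resamples (with replacement) per class per
  epoch; every presentation freshly composed, so the model effectively
  never sees the same input twice.
- **earlystop**: up to 40 epochs, stopping when fraction correct on a fixed
  80+80 validation set (composed once, before training) fails to *strictly*
  improve for 5 consecutive epochs; 400 resamples per class per epoch.
  Used by the gender task, where the pool is smaller and overfitting risk
  higher.

Prediction: face iff w·f + b > 0, ties to non-face.

## Evaluation

Each experiment repeat draws a fresh class-wise random split (50/50, or
50/10/40 with validation), trains on the training half, and runs one
forward pass over freshly composed canvases resampled from the test half —
fully cross-validated.  Reported: percent correct, hit rate, false-alarm
rate, and the sensitivity index d' = Z(hit) − Z(false alarm).  Rates are
clamped to [0.005, 0.995] before the probit transform, so the symmetric
ceiling is exactly 2·Z(0.995) = 5.15, and d' is clipped there.  Medians
over repeats summarize each condition; full distributions are exported.

Repeat i uses seed base_seed + i with independent sub-streams for
splitting, initialization, and the resample/composition stream.  Because
the composed canvas stream does not depend on the model, all requested
model kinds train per repeat on a *shared* stream (the reference protocol
trained them in separate runs; sharing changes no per-model marginal
distribution and lets the Gabor responses be computed once for the three
V1 variants).  Sharing split seeds across conditions acts as common random
numbers, tightening between-condition comparisons.

## Lesions

Two families, both re-initializing and retraining the readout on the
reduced feature set, at a fixed reference condition (50% scale, ±45°
rotation, blurred-scene background):

- **Channel lesions** drop or keep whole spatial-frequency channels;
  surviving kernels are untouched.
- **Consistency lesions** keep (or drop) units whose trained weight sign
  was identical and nonzero in at least a threshold number of full-model
  runs.  Exactly-zero weights count as inconsistent (an explicit rule;
  zero has measure zero under continuous training).  Kept sets are nested
  across thresholds by construction.

## The packaged benchmark

The reference experiments (100 splits, 1,500 resamples/class/epoch,
~1,700 images per class) cost hours per condition on one CPU.  The packaged
benchmark keeps the protocol and shrinks the scale; all sizes are package
choices fixed in `earlyvision.benchmark`:

| experiment | pool | cfg | test | repeats |
|---|---|---|---|---|
| ordering (mid-gray, no scale/rotation variation) | 120/class | 6 epochs x 200/class, batch 2 | 250/class | 8 |
| rotation trend (mid-gray, 50% scale, rot 0–180°) | 120/class | 4 epochs x 150/class, batch 4 | 150/class | 6 |
| lesion reference (blurred scene, 50%, 45°) | 120/class | 4 epochs x 150/class, batch 4 | 150/class | 6 |

Composed canvases are the expensive resource at this scale, so the batch
size shrinks (to 2 in the ordering cell, 4 elsewhere) to keep the number
of SGD steps comparable to the full protocol's several hundred; the
ordering cell uses the smallest batch because the simple model (4x more
inputs than complex) needs the most steps to approach its ceiling, and
comparing families mid-convergence would measure optimization speed
rather than representation.  Encoding runs in float32 here.  At this scale the benchmark measures *orderings and
trends* (simple ≈ complex, both above LGN and linear; performance
non-increasing with rotation range; consistency-kept models matching the
full model), not the absolute medians of the full-scale study.

## Known limitations

- Absolute percent-correct values depend on the synthetic generator and
  benchmark scale; only structural comparisons are meaningful.
- The gender task uses parametric feature-geometry variants, a much
  cleaner signal than human-labeled photographs.
- Medians over ~6–10 repeats carry noticeable sampling noise; the common
  random-number seeding is what makes adjacent-condition comparisons
  usable at this scale.
- The readout is the only trained component by design; no conclusions
  about learned feature hierarchies can be drawn from this package.
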