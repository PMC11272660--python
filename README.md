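# earlyvision

How much can the *first* stages of visual processing tell you about what
you are looking at?  `earlyvision` models the earliest cortical and
thalamic encoders — V1 simple cells (oriented Gabor filters with
half-rectification), V1 complex cells (phase-pooled energy units), V1
linear receptive fields, and LGN-like center-surround (difference-of-
Gaussians) units — as fixed convolutional filter banks, trains a single
linear readout on top of them, and measures how well that readout
separates face-like from non-face stimuli as scale, orientation, position,
and background clutter vary.  It is aimed at visual neuroscientists and
modelers who want a tested, reproducible pipeline for "how far does a
retinotopic, linearly-decoded early-vision code get you" experiments.

The encoders tile a 340x340 canvas with four spatial-frequency channels
(carrier wavelengths λ = 256, 128, 64, 32 px, stride λ/2, envelope SD
0.4λ, support 1.5λ), giving 7,088 simple / 1,772 complex / 3,544 linear /
886 LGN units.  The readout is w·f + b trained with SGD (lr 0.01,
momentum 0.9) on the binary cross-entropy-with-logits loss, every training
and test canvas freshly composed (random scale u ~ U[s_min, 1], rotation
ρ ~ U[−r, +r], jitter ±42 px, fresh background) so the model never sees
the same input twice.  Performance is summarized by the median over
repeated random 50/50 splits of percent correct and the sensitivity index

    d' = Z(hit rate) − Z(false-alarm rate),

rates clamped to [0.005, 0.995] so d' saturates at 5.15.  Simulated
lesions remove spatial-frequency channels or weight-sign-inconsistent
units and retrain the readout.  Because the original face/object/scene
photo sets are not distributable, a synthetic generator produces
luminance- and contrast-matched face-like and non-face stimuli with the
published shape statistics (fraction filled, elongation); see
`docs/methods.md` for what that does and does not license.

## Worked example

```python
import numpy as np
from earlyvision import FaceDecoder, Condition, BackgroundSpec, NuisanceSpec
from earlyvision.readout import TrainConfig

dec = FaceDecoder.from_generator(
    n_per_class=40, seed=7,                  # synthetic matched pool
    model_kind="simple",
    condition=Condition(BackgroundSpec("mid_gray"),
                        NuisanceSpec(scale_min=1.0, rot_max=0.0)),
    train_config=TrainConfig(epochs=6, per_class=150, batch_size=2),
    dtype=np.float32)
res = dec.fit(seed=0, n_repeats=3, test_per_class=200)
print(res.summary())
```

```
FaceDecoder Results
==========================================================
Encoder:            V1/LGN bank 'simple'
Units (by channel): 7088  (144, 144, 1024, 5776)
Background:         mid_gray
Scale range:        [1.00, 1.00]
Rotation range:     +/-0 deg
Jitter range:       +/-42 px
Protocol:           fixed (6 epochs, 150/class/epoch)
Pool:               40 face / 40 nonface
Repeats:            3
----------------------------------------------------------
Median percent correct: 0.795
IQR percent correct:    [0.751, 0.809]
Median hit rate:        0.635
Median false alarms:    0.120
Median d':              2.041
==========================================================
```

The readout reaches ~80% cross-validated accuracy (d' ≈ 2.0) from V1
simple-cell features despite ±42 px position jitter on every presentation
— a coarse face/non-face decision is linearly decodable from an early,
retinotopic code.  Each of the 3 repeats is an independent random split of
the pool, trained on ~900 freshly composed canvases; the conservative
hit/false-alarm balance at this small scale reflects a readout still
biased toward the non-face side of the boundary.

The same experiment from the shell:

```bash
earlyvision grid --n 40 --models simple,lgn --repeats 3 \
    --epochs 6 --per-class 150 --test-per-class 200 \
    --seed 7 --out results.csv
earlyvision report results.csv
```

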