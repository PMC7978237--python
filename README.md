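# cineseg

Semantic segmentation of thyroid ultrasound **cineclips** — video recordings
of a transducer sweep across the neck in the transverse plane.  The package
implements a recurrent dual-output segmentation framework end to end:

- a DeepLab-style encoder (three-convolution input stem, four residual
  bottleneck stages with dilation rates 2 and 4 replacing the last two
  strides, atrous spatial pyramid pooling at output stride 8, and four
  skip-fusion steps), with **two output heads**: a sigmoid head for the
  thyroid gland and a 3-class softmax head for background/cyst/nodule.
  Separate heads let a lesion overlap the organ without carving holes into
  the organ mask;
- a **recurrent module** for 6-frame windows: the frozen pretrained encoder
  is replicated across the window (two groups of three), and per group four
  blocks of paired forward/backward convolutional LSTMs run at dilations
  1, 3, 5, 7 (concatenate + batch-norm + LeakyReLU after each pair),
  followed by one final forward and one final backward ConvLSTM over the
  merged sequence — 18 ConvLSTM layers in total, each 3×3 with 32 filters
  at full width;
- a **class-balanced soft-MCC loss**.  For a probability map *p* and binary
  target *y*, soft counts TP = Σ w·p·y, FP = Σ w·p·(1−y), FN = Σ w·(1−p)·y,
  TN = Σ w·(1−p)·(1−y) (w = weight of the pixel's true class, with
  background and thyroid down-weighted) enter

      MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

  and the loss is 1 − mean(MCC) over heads and classes.  Unlike overlap
  losses, it back-propagates a useful gradient even when a class has no
  positive pixel in the target;
- a **four-stage training protocol** (thyroid-only pre-training → dual
  output with 2/3 forced-nodule batches → frozen-through-ASPP sequence
  fine-tuning → recurrent training), with the per-stage augmentation table
  (flips, bounded rotations/translations, intensity shifts, crops, sequence
  reversal);
- evaluation metrics IoU, MCC, recall, precision and F2 = 5TP/(5TP+4FN+FP),
  ROC curves, stratified report tables, slice-integral vs ellipsoid
  ((π/6)·L·W·H) **volume estimation**, and a seeded
  **distance-regularized level-set (DRLSE)** baseline;
- a **synthetic cineclip generator**: sweep phantoms built by uniform-
  velocity planar slicing of 3-D ellipsoids (thyroid band, hypo/iso/hyper-
  echoic nodules, anechoic cysts) under unit-mean Gamma speckle, with exact
  ground-truth masks, configurable margins (smooth / ill-defined /
  lobulated) and per-frame "flicker" obscuration that only temporal context
  can see through.  Everything in the package is exercisable on these
  phantoms without any clinical data.

No deep-learning framework is required: the models run on a compact
numpy-based autodiff core shipped in `cineseg.nn` (convolutions via
im2col, transposed convolutions, batch normalization, ConvLSTM cells,
Adam), verified against finite-difference gradients.

## Worked example

```python
import numpy as np
from cineseg.cine_io import split_by_patient
from cineseg.model_zoo import tiny_config
from cineseg.synthetic_cine import generate_cohort
from cineseg.trainer import cohort_from_manifest, evaluate_model, run_full_protocol

clips, manifest = generate_cohort(20, seed=111, flicker_prob=0.3)
manifest = split_by_patient(manifest, (0.6, 0.2, 0.2), seed=111)
cohort = cohort_from_manifest(clips, manifest)

state, histories = run_full_protocol(tiny_config(), cohort, seed=0)
print({s: round(h[-1]["loss"], 3) for s, h in histories.items()})
report = evaluate_model(state.recurrent_model, cohort["validation"])
print({c: round(m["iou"], 3) for c, m in report.items()})
```

Printed output from this exact run (a few minutes on one CPU):

```
{1: 0.206, 2: 0.343, 3: 0.457, 4: 0.342}
{'thyroid': 0.771, 'cyst': 0.011, 'nodule': 0.199}
```

The per-stage numbers are the final-epoch training losses (1 − mean soft
MCC; 0 is perfect).  The second line is mean per-clip IoU on held-out
validation phantoms: the thyroid band is segmented well at this desk
scale (IoU 0.77), while nodules — roughly 2% of pixels — and the even
rarer cysts are detected only coarsely, mirroring the clinical difficulty
ordering of the three classes.  The same protocol at full width and
256×256 resolution is configuration, not new code.

A command-line interface wraps the same library surface:

```bash
cineseg simulate --patients 20 --out data/ --seed 7
cineseg split --manifest data/manifest.json --fractions 0.6,0.2,0.2 --seed 7
cineseg train --data data/ --out runs/ --stages 1,2,3,4 --seed 7
cineseg segment --model runs/recurrent.npz --clip data/P000_0.tiff --out masks/
cineseg evaluate --pred masks/ --truth data/ --report report.json
cineseg volume --pred masks/ --spacing 1,1,1 --out volumes.json
cineseg drls --image frame.tiff --seed-mask seed.tiff --out drls.tiff
```

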