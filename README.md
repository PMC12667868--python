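# stomaseg

Semi-automated stomatal phenotyping from fluorescence micrographs.

Stomata — the paired guard-cell pores that control gas exchange on the
leaf surface — are routinely quantified by hand-tracing their outlines in
confocal images of plasma-membrane reporter lines, a major bottleneck for
population-scale studies of stomatal size, density and pairing.
`stomaseg` automates that annotation step: a lightweight learnable
segmenter produces per-pixel stomatal masks from grayscale micrographs, a
fixed morphological repair chain cleans them, and downstream modules
score the results against ground truth, extract per-stoma morphometrics,
and flag stomatal clusters.

## What it does

- **Sliding-window segmentation** — images are processed in 128×128
  windows with 16 px overlap. Each window yields per-pixel scores on
  (−∞, ∞) ("logits"); overlapping windows are combined by their mean and
  encoded as a 0–255 confidence map via `round(255·σ(x))`, where σ is the
  logistic function. Training resamples the augmentation of every tile
  each epoch: one of the 8 square-symmetry variants (1–4 quarter turns ×
  optional vertical flip), plus a 1/3-probability Gaussian blur (kernel
  ∈ {3,5,7}, σ ∈ [0,3]) on the image only.
- **Mask repair** — Otsu thresholding, removal of objects > 3750 px,
  open/close smoothing (disk radius 3), removal of objects < 250 px
  (deliberately after smoothing), hole filling.
- **Evaluation** — pixel contingency and IoU = TP/(TP+FP+FN); a
  margin-band fold error (total pixel error ÷ boundary-band pixels, < 1
  acceptable); per-object Complete / Partial / False / Miss calls with a
  3 px boundary tolerance.
- **Morphometrics** — per-stoma area, perimeter, eccentricity
  `√(1−(b/a)²)` and moment-ellipse length/width; population summaries
  and densities.
- **PairCaller** — classifies each mask component as a single stoma or a
  cluster (≥ 2 stomata in contact) from 72×72 crops, trained with random
  jitter so it cannot key on exact centring.
- **Synthetic scenes** — a seeded generator draws fluorescence-like
  epidermis images (bright pavement-cell wall networks, guard-cell pairs
  around a dark pore slit) with exact ground truth, so the entire
  pipeline trains and validates without real data.

## Worked example

```python
from stomaseg import StomaSegmenter, SceneSpec, evaluate_dataset, measure_objects
from stomaseg.synth import scene_batch

train = scene_batch(SceneSpec(), 20, seed=101)   # 320x320 scenes, 6 stomata each
val   = scene_batch(SceneSpec(), 5,  seed=202)

seg = StomaSegmenter(epochs=15, random_state=7)
seg.fit([s.image for s in train], [s.truth_mask for s in train],
        [s.image for s in val[:2]], [s.truth_mask for s in val[:2]])

pairs = [(s.truth_mask, seg.predict(s.image)) for s in val]
df, total = evaluate_dataset(pairs)
print(df[["hit", "miss", "partial", "false", "total", "iou"]])
print("positive rate:", total["positives"] / total["total"])
print("mean IoU:", round(total["mean_iou"], 3))
```

prints (exact IoU digits vary with BLAS build):

```
   hit  miss  partial  false  total       iou
0    5     0        1      0      6  0.955191
1    3     0        3      0      6  0.940853
2    2     0        4      0      6  0.942448
3    2     0        4      0      6  0.926305
4    3     0        3      0      6  0.952522
positive rate: 1.0
mean IoU: 0.943
```

Every held-out stoma was identified (Complete or Partial — "positive
rate" pools both, as a human proofreader can promote a Partial call with
a few clicks), no stomata were missed or hallucinated, and the predicted
masks overlap the truth at a mean IoU of 0.94. `measure_objects(mask,
pixel_size=0.57)` then turns any mask into per-stoma records in µm.

The same pipeline is scriptable from the shell: `stomaseg synth`,
`train`, `predict`, `postprocess`, `evaluate`, `measure`, `paircall` —
see `stomaseg --help`.

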