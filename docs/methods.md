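# Methods

## Problem setting

Input images are 2D grayscale fluorescence micrographs of the leaf
epidermis (plasma-membrane reporter signal, already max-projected
upstream), in which stomata appear as paired kidney-shaped guard cells
around a dark pore slit, embedded in a bright polygonal network of
pavement-cell walls. Ground-truth annotations are same-shape binary
masks stored as strictly black/white (#000000/#FFFFFF) PNGs in which
each white blob occludes one stomatal complex — or several, when stomata
touch. All coordinates are row-major and 0-based with the origin at the
top-left; bounding boxes are half-open; connected components are
8-connected, so diagonally touching guard-cell junctions stay one
object.

## Segmentation model

The segmenter classifies every pixel of a 128×128 window as
stoma / not-stoma. Each pixel is described by a bank of multiscale,
rotation-invariant local features — Gaussian-smoothed intensity,
gradient magnitude, and the two Hessian eigenvalues at σ = 1, 2, 4, 8,
16 px (20 features) — and scored by a small fully connected network
(two hidden layers, 32 and 16 units, ReLU) trained with the
adaptive-moment optimiser at learning rate 0.001 under per-pixel binary
cross-entropy, the canonical objective for two-class semantic
segmentation. The feature scales cover the structures that
distinguish a stoma from its surroundings: thin bright walls (1–2 px),
the pore slit and guard-cell membrane texture (2–8 px), and the
whole-complex context (8–16 px).

Training data preparation:

1. Each (image, mask) pair is tiled into 128×128 windows whose origins
   advance by stride 112 (= window − 16 px overlap) along each axis; an
   extra edge-flush origin is appended whenever the last regular origin
   misses the far edge, so every pixel is covered and no padded border
   statistics enter training.
2. Each epoch, every tile is replaced by one freshly drawn augmentation
   variant: uniform over the 8-element square-symmetry orbit (1–4
   quarter turns × optional vertical-axis flip, applied identically to
   image and mask), then with probability 1/3 a Gaussian blur of the
   image tile only (kernel size uniform on {3, 5, 7}, σ uniform on
   [0, 3]). Masks are never blurred — labels must stay binary. Quarter
   turns are counter-clockwise; the orbit is direction-independent, the
   choice is fixed purely for determinism.
3. From each augmented tile, 200 pixels are sampled stratified by class
   (up to half foreground) and fed to one `partial_fit` step per epoch.

Per-epoch train and validation losses are logged; when validation pairs
are supplied, the checkpoint with the best validation loss is kept.
Epoch seeds, pixel sampling and weight initialisation all derive from a
single `random_state`, so single-threaded training is reproducible
bit-for-bit.

Inference slides the same window geometry over the full image. Window
scores are log-odds transformed from the network's class probabilities
(clipped at 1e−12 for numerical hygiene, far outside the ±12 magnitude
seen in practice); overlapping contributions are combined by their
arithmetic mean *in logit space* — symmetric, calibration-friendly, and
recorded per pixel in a contribution-count raster (1, 2 or 4
contributors under the default geometry). The composite is encoded as
`round(255·sigmoid(logit))`, a 0–255 confidence map with the same extent
as the input; 0 means ~0% and 255 ~100% confidence that the pixel lies
inside a stoma. Images smaller than the window are rejected with
guidance rather than padded, since padding would inject border
statistics never seen in training.

## Mask repair

The confidence map is converted to a clean binary mask by a fixed
chain: (1) Otsu thresholding over the 256-bin histogram (strictly-above
pixels become foreground; a constant map yields an empty mask plus a
warning); (2) removal of objects larger than 3750 px — larger than any
real stomatal complex or hydathode; (3) smoothing by morphological
opening then closing with a disk of radius 3, which removes branch-like
projections a few pixels wide; (4) removal of objects smaller than
250 px — smaller than any real stoma — placed after smoothing on purpose,
because the open/close step can strand small fragments; (5) filling of
interior holes (pore lumina). Both size gates are strict inequalities:
areas of exactly 250 or 3750 px survive.

Two choices here were genuinely open. The large-object filter is
applied after thresholding (component area is ill-defined on a grayscale
map), while the relative order of all remaining steps — including
small-object removal last — is preserved. And "smoothing" is
operationalised as open-then-close with a configurable disk radius
(default 3): large enough to delete 1–2 px spurs, small enough to leave
guard-cell bodies intact. Open-then-close is idempotent, a property the
tests exploit.

## Evaluation

Per-pixel: the contingency table (tp, fp, fn, tn), IoU = tp/(tp+fp+fn)
(defined as 1 when both masks are empty), total pixel error = fp + fn,
and a margin-normalised *fold error magnitude*: total pixel error
divided by the number of margin pixels, where the margin band is
`dilate(truth, r) XOR erode(truth, r)` — the thin ring around every
ground-truth boundary where annotator and machine may legitimately
disagree. A fold error below 1 means the total discrepancy would fit
inside that band. The default band radius is 1 (a ~2–3 px ring); it is
an estimate, configurable, and the fold-error *arithmetic* is
independent of it.

Per-object: truth and prediction components are matched greedily by
descending pairwise IoU (deterministic; zero-overlap pairs never match;
equivalent to optimal assignment in non-pathological cases). A matched
truth object is **Complete** when the symmetric maximum
boundary-to-boundary distance (Hausdorff distance between outlines,
via distance transforms) is at most 3 px, else **Partial**; an
unmatched truth object is a **Miss**; an unmatched prediction is
**False**. The single deviation measure captures both failure
directions — over-segmentation beyond the outline and failure to reach
it. Report aggregation pools counts: `% accurate` = ΣComplete/Σtotal,
and `positives` = ΣComplete+ΣPartial (both are reported, since a
proofreading workflow can promote Partial calls cheaply). The
concordance overlay colours false negatives blue (#0000FF), false
positives orange (#FF8000), true positives pink (#FF80FF) and true
negatives black.

## Morphometrics

Per 8-connected component: area (pixel count), perimeter (contour
estimator with diagonal correction — absolute values are
estimator-dependent, so the estimator is part of the contract),
eccentricity and ellipse-equivalent major/minor axis lengths from the
second central moments. "Length" and "width" are the moment-ellipse
axes rather than bounding-box extents: they are rotation-invariant and
match the intuitive long/short axis of a guard-cell complex. Supplying
a pixel size (e.g. µm/px) scales lengths linearly and areas
quadratically. Stomatal density divides the count by a reference area —
by default the full image, optionally a tissue outline.

## PairCaller

Clusters (≥ 2 stomata in direct contact, violating the one-cell-spacing
rule) form a single mask component. Each component is classified from a
72×72 px crop centred on its centroid — large enough for most single and
clustered complexes; larger objects are centre-cropped, never rescaled.
The crop has two planes: the micrograph and the component's own mask
(isolated from neighbours). Planes are downsampled to 24×24 and
complemented by six full-resolution outline descriptors of the mask
plane (area fraction, eccentricity, axis ratio, solidity, compactness,
bounding-box extent — small touching clusters differ from elongated
singles mainly by a waist and a second pore slit, and downsampling
erodes that signal); the concatenation is scored by a one-hidden-layer
network (64 units). Training crops are jittered
by uniform integer offsets in [−8, +8] px per axis — enough displacement
that centring is uninformative while a typical stoma stays in the
field — so the classifier must use object-intrinsic structure;
inference always uses the centred, un-jittered crop. The decision
threshold on the cluster probability is 0.5.

## Synthetic scenes

The generator emulates the qualitative structure of the real images,
not their photometric detail: a seeded Voronoi tessellation rendered as
~3 px bright ridges (pavement-cell walls) over a dark interior; stomata
as bright-outlined filled ellipses with a dark 1–3 px pore slit along
the major axis and denser interior signal; clusters as 2–3 slightly
overlapping member ellipses sharing one truth component; optional
pore-less outline-only distractors (immature stomata, the hard-negative
class the segmenter must ignore) and an optional low-frequency
multiplicative shading field; additive Gaussian noise and optical blur
on top. Defaults describe a realistic 20x-confocal field: 320×320 px
scenes with 6 stomata (matching the stomatal density of 512×512
validation segments carrying ~15), areas 600–2400 px² (safely inside
the 250/3750 px repair gates), eccentricities 0.55–0.85, wall density
2 cells per 10⁴ px², noise σ = 8, blur σ = 1. Area targets are drawn
from the inner 80% of the requested interval so digitisation never
pushes a component outside it.

Truth masks are regularised at generation time by the same open/close
(radius 3) used in mask repair — guard-cell outlines are smooth and
spur-free by construction — which, by idempotence, makes an ideal
confidence map an exact fixed point of the repair chain. Placement
keeps distinct objects ≥ 12 px apart so the closing can never merge
them; placement failures after bounded retries raise rather than
silently under-filling.

What passing synthetic benchmarks does and does not show: the scenes
exercise every pipeline contract (tiling, augmentation statistics,
compositing, repair, scoring, pair calling) and a realistic
figure-ground geometry, but they lack the intensity heterogeneity of
real tiled cotyledon acquisitions, out-of-focus tissue, developmental
shape diversity and annotator noise. Detection and IoU figures on
synthetic scenes are therefore upper bounds on real-data performance,
not estimates of it.

## Problem sizes and numerical choices

The reference benchmarks train on 20 scenes for 15 epochs and evaluate
5 held-out scenes; the pair-classifier benchmark uses 100 half-clustered
scenes (≈ 500 single / 500 clustered crops, 80/20 train/test). These
sizes give stable pass/fail behaviour across seeds at desk scale.
Other fixed choices: Otsu agreement is verified against an exhaustive
256-threshold between-class-variance search; logits are clipped only
through the probability floor 1e−12; `round(255·σ(0)) = 128` defines
mid-scale; all seeds derive from a single integer and stay below 2³¹.

## Known limitations

- The per-pixel classifier sees a 16 px neighbourhood at most; very
  large or unusually textured complexes rely on the repair chain.
- Greedy IoU matching can differ from optimal assignment in dense
  many-to-many overlap configurations not seen in these data.
- The margin-band radius behind the fold error is an estimate (default
  1); absolute fold errors are comparable only at a fixed radius.
- Training determinism is guaranteed single-threaded; multi-threaded
  BLAS reductions may perturb the last few bits across machines.
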