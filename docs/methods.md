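# Methods

## Problem and pipeline

Spray-dried fruit and vegetable powders are produced from juice plus a
carrier (potato maltodextrin). Two process parameters dominate the
product's appearance: the dry-juice content of the powder (here 30, 40
or 50 %, the remainder being carrier) and the carrier's degree of
saccharification (dextrose equivalent DE 12 = "L", DE 26 = "H"). Juice
content controls the anthocyanin load and therefore the powder's dyeing
force — more juice gives a redder, more saturated, slightly darker
powder — while the saccharification level shifts appearance only
subtly. `powdervision` classifies powder tiles by these labels from
color statistics alone:

1. **Tiling** (`imaging`): photographs are cut into equal square tiles
   (default 400 × 400 px), row-major from the top-left; partial edge
   tiles are discarded rather than padded so all tiles share the same
   pixel-count statistics.
2. **Descriptors** (`colorspace`, `features`): each tile is reduced to
   46 numbers — max, mean, median, min and population standard
   deviation of R, G, B (native), Y, Cb, Cr (BT.601 full-range), S, V
   (HSV) and L (HSL), plus the mean hue of chromatic pixels.
3. **Classifier** (`mlp`): a 46-11-10 multilayer perceptron with
   logistic activations, trained by back-propagation and refined by
   conjugate gradient, with a reject option producing Unknown answers.
4. **Interpretation** (`interpret`): error-quotient sensitivity
   ranking of the 46 inputs, then PCA of the correlation matrix of the
   top-ranked descriptors.

## Descriptor conventions

* **YCbCr matrix.** Full-range ITU-R BT.601 (the JPEG convention):
  white → (255, 128, 128), grays → Cb = Cr = 128. Consumer-camera
  pipelines emit full-range chroma, which is why it is the default;
  the studio-range matrix is available as `matrix="bt601-studio"`.
* **Hue.** Degrees in [0, 360), defined identically for HSV and HSL,
  set to 0 for achromatic pixels. `H_mean` is the *arithmetic* mean
  over chromatic pixels: powders occupy a narrow red-pink hue arc far
  from the 0/360 wrap, where the circular mean (available via
  `circular_hue=True`) coincides with the arithmetic one.
* **Scales.** R, G, B, Y, Cb, Cr on 0–255; S, V, L on 0–1; hue in
  degrees. Mixed natural scales are harmless because the network
  standardizes every input on the training rows.
* **Standard deviation.** Population denominator N throughout: a
  tile's pixels are the entire population being summarized, not a
  sample from a larger one.
* **Exactness of the fast path.** Statistics of integer-valued
  channels (R, G, B, and V, L through the pixelwise max/min) are
  computed from 8-bit histograms with a two-pass mean/variance; this
  is bit-comparable (≲ 1e-15) to the naive per-pixel computation and
  covered by an equality test against it.

## The classifier

The ten output units decompose as 6 + 3 + 1: a one-of-N code for the
sample number (1–6), a one-of-N code for juice content (30/40/50), and
a single two-state unit for saccharification (H = 1). This is the only
decomposition of the three categorical outputs consistent with ten
output units. The loss is the sum of squared output errors; the
monitored metric is RMS over all (case, unit) elements, which stays in
[0, 1] for unit-interval targets.

Training schedule and defaults:

* **Back-propagation**: 50 epochs of per-case stochastic gradient
  descent, learning rate 0.1, momentum 0.3, rows reshuffled each epoch
  with the run seed. These are conventional simulator defaults; both
  are exposed.
* **Conjugate gradient**: up to 119 full-batch Polak–Ribière (PR+)
  iterations with an Armijo backtracking line search (c₁ = 1e-4); a
  failed search restarts as steepest descent, a second failure stops.
  The loss sequence over accepted iterations is non-increasing by
  construction. The weights returned are those with the lowest
  *validation* RMS seen, so late over-fitting cannot degrade the
  model.
* **Initialization**: seeded uniform [−0.5, 0.5] weights and biases.
* **Split**: seeded shuffle into 2:1:1 training/validation/test,
  sizes (round(n/2), floor(n/4), remainder) with half-up rounding, so
  4218 rows give 2109/1054/1055.

**Reject option.** A multi-unit head answers only if its winning
activation reaches the acceptance threshold (default 0.5), otherwise
Unknown. The single saccharification unit answers H at ≥ threshold and
L at ≤ 1 − threshold; its reject band is therefore empty at the
default threshold and only opens for thresholds above 0.5. Unknown
answers count against accuracy (accuracy = correct/total), and every
report cell satisfies total = correct + wrong + unknown.

A separate *pruning threshold* of 1.05 appears in the sensitivity
report: variables with error quotients below it are flagged as
candidates for removal. The two thresholds are distinct concepts and
deliberately not conflated; nothing is ever dropped automatically,
since low-ranked variables can still carry joint information.

## Sensitivity analysis

Baseline error is the validation RMS. Each input in turn is suppressed
by replacing it with its training-set mean (zero after
standardization — classic missing-value substitution; a permutation
variant is available), and the quotient is suppressed/baseline.
Quotients above 1 mean the network deteriorates without the variable;
a variable constant across rows gives exactly 1. Quotients are ranked
descending with ties broken by canonical column order. A zero baseline
makes quotients undefined and raises — in practice it signals a toy
problem without irreducible error, where the quotient of an irrelevant
feature degenerates into a ratio of numerical residues (observed as
quotients far from 1 on a fully separable toy task; the packaged toy
benchmark therefore uses overlapping classes, within-class SD 0.7 at
class-mean distance 2, n = 400).

## PCA

PCA operates on the Pearson *correlation* matrix of the top-k
(default 15) descriptors, so eigenvalues sum to the number of
variables p and each eigenvalue's share 100·λ/p is its percent of
variance. For a printed, 2-decimal matrix the completion is not exactly
positive semi-definite: tiny negative eigenvalues (|λ| < 0.012 for the
packaged fixture) are clipped to 0, which can push the scree sum a few
tenths of a percent above 100. Loadings are eigenvectors scaled by
√λ, signs fixed so each component's largest-magnitude loading is
positive. The packaged fixture (`data/published_correlation_15.csv`)
holds the published lower-triangular matrix of the 15 most sensitive
descriptors; its decomposition gives a leading eigenvalue of 10.22
(68.2 % of variance) and a two-component cumulative share of 84.1 %.

## Synthetic data: what it emulates, and what not

The generator draws per-pixel color as base_rgb + independent
per-channel Gaussian noise (default SD 8), quantized to 8 bits, with a
Bernoulli fraction (default 6 %) of pixels darkened by a factor 0.75
to mimic granular shadows in matte powder. The six default class specs
form the full {30, 40, 50} % × {L, H} design; the red channel rises
(and green/blue fall) monotonically with juice content, and the L→H
offset is a small brightness shift (≤ 7 per channel), deliberately
smaller than the juice-content effect, making saccharification the
hardest label — mirroring its lowest published accuracy. All outputs
are pure functions of (spec, dimensions, seed); tiles are generated at
tile size directly (the tiler is validated separately on full-scene
rasters).

What the generator does *not* model: optics, illumination gradients,
specular highlights, particle-size texture, container edges, or any
chemistry of drying. Consequently, passing recovery tests show the
pipeline can extract class structure that is present in mean color and
noise statistics — they do not certify performance on real
photographs, where descriptor distributions are broader and tile-level
outliers exist. The degenerate control (all six classes sharing one
base color) verifies the other direction: with no class signal,
forced-choice sample-number accuracy is statistically indistinguishable
from the 1/6 chance level. That control is evaluated at acceptance
threshold 0, because under the default reject rule a no-information
network answers Unknown everywhere and its accuracy (0) would test the
reject mechanism rather than chance behaviour.

## Problem sizes used by the test bench

The full-scale recovery check runs the complete pipeline at the study's
scale — 703 tiles per class (4218 total) of 400 × 400 px — for three
seeds, and requires juice-content test accuracy ≥ 0.95 and
sample-number test accuracy ≥ 0.90. Unit and property tests use small
tiles (8–64 px) and small tables, which exercise identical code paths;
tile size only changes the variance of tile-level descriptors.

## Known limitations

* The YCbCr variant actually used by the original acquisition software
  is unknown; absolute Cb/Cr values are convention-dependent, so no
  check relies on absolute YCbCr values from the original images.
* Only the hue *mean* is computed (the published descriptor list has
  no other hue statistics); the arithmetic hue mean would be wrong for
  hue distributions straddling 0/360, which powders do not exhibit.
* BP hyperparameters and weight-initialization ranges in the original
  study are unreported; the defaults here are conventional and the
  end-to-end results on synthetic data are insensitive to them at the
  separations the generator produces.
* The published tile count (~4218 from 127 scenes of 4928 × 3264)
  implies an unstated subsampling rule; the generator exposes
  `n_tiles_per_class` rather than guessing it.
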