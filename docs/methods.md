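# Methods

## Model

`milniche` is a multiple-instance learning (MIL) pipeline for multiplexed
tissue images. A *sample* is one H×W×N marker image with a binary outcome
label; an *instance* (crop) is one of the M = 30 most irregularly shaped of
100 SLIC superpixels, carried as an h×h×N patch plus a binary membership
mask. The working assumption is that superpixels deviating from a compact
quadrilateral straddle dense, heterogeneous cellular neighbourhoods and are
therefore the informative parts of the tissue, while near-rectangular
superpixels sit on homogeneous background.

The instance scorer is a fully convolutional network (stride-1 3×3
convolutions with ReLU, a 1×1 embedding layer of width d, a 1×1 class head,
per-location softmax), so each crop yields a dense map of per-location class
probabilities at full crop resolution (h′ = h). The bag-level aggregation is
quantile-based: per class, the probabilities at mask-valid locations of all
crops in the bag are pooled and sorted, and Q order statistics are selected
at 1-based index ⌈n·(q−½)/Q⌉, q = 1..Q. The concatenated K·Q quantile
vector V feeds a linear readout plus softmax that produces sample-level
class probabilities; the categorical cross-entropy over samples trains
network and readout jointly. The readout is initialised at the block-sum
pattern (class logit = sum of that class's quantile values), so an untrained
model reduces to a softmax over per-class quantile sums; the notationally
convenient "softmax of V" is dimensionally K·Q → K, and a trained linear
readout is the aggregation-module parameterisation that makes it
well-defined. Quantile selection is a hard index pick: gradients flow
through the selected values only, exactly as in max-pooling.

Crop embeddings are mask-averaged penultimate-layer features (d values per
crop). A random forest over crop embeddings (labels inherited from the
sample) is explained with exact path-dependent tree-SHAP; a crop's
importance is the absolute sum of its SHAP values for the positive class.
Importance maps paint each of the per-image top-20 prioritised superpixels
with its crop's importance. Sample featurisations are either the mean
embedding of those top-20 crops (MI features) or cluster frequencies from a
global k-means over crop embeddings (K = 30). Outcome prediction uses a
random forest over repeated random folds (default 200) that are grouped by
donor and stratified by donor-level label; the headline statistic is the
mean ± sd of per-fold AUROCs, with the AUROC of fold-averaged per-sample
probabilities reported alongside.

## Numerical and implementation choices

- **Network and training.** The FCN and its backpropagation are implemented
  directly on numpy arrays (im2col products, float32); Adam with one bag
  per step, all randomness seeded. Library defaults: h = 64, width 32,
  depth 4, d = 64, Q = 8, lr 1e-3. The readout learning rate is scaled by
  0.1: it has few parameters on a direct gradient path and otherwise
  absorbs the loss before the convolutional features learn anything.
- **Quantile resolution.** Q must resolve the expected fraction of
  informative tissue: the top rank sits at percentile (Q−½)/Q, so a signal
  occupying the top f of pooled probabilities is invisible unless
  1/Q ≲ f. The desk-scale configuration uses Q = 128 because the planted
  signal in the synthetic images occupies ~1–2% of pooled mask pixels.
- **Tree-SHAP.** The path-dependent polynomial algorithm (extend/unwind
  over the decision path), numba-compiled over sklearn tree arrays,
  validated in the test suite against brute-force Shapley enumeration on
  the cover-weighted conditional expectation. Local accuracy (Σφ + base =
  predicted probability) holds to ~1e-15 and is asserted at 1e-6.
- **SHAP forest regularisation.** The crop-level forest keeps 200 trees and
  unlimited depth but uses `min_samples_leaf=5`: with singleton leaves the
  forest memorises the (inherently noisy) inherited labels of uninformative
  crops and Σ|φ| acquires a spurious baseline that drowns genuine signal
  attribution.
- **Normalisation.** Raw intensities are arcsinh-transformed (cofactor 5),
  clipped at the per-channel 99th percentile and scaled to [0, 1] —
  standard IMC practice; both knobs are configurable.
- **Crop geometry.** Margin = 25% of the larger bounding-box side, capped
  at 16 px; pad-to-square then bilinear resample for patches,
  nearest-neighbour for masks; a mask that vanishes under downsampling
  keeps its centroid pixel. Ties in irregularity break by ascending
  superpixel id; the SLIC seeder is re-targeted upward when it degenerates
  to a single segment at very small segment counts.
- **Degenerate inputs.** Empty validity rasters fall back to all locations
  with a logged warning; true-class probabilities are clamped at 1e-12 in
  the loss; all-equal abundance frequencies stratify deterministically by
  sample id with a warning.
- **Permutation null.** The shuffled-label control redraws a donor-level
  label permutation *per fold*. A single fixed permutation is not centred
  at 0.5 on small cohorts: every fold re-learns the same spurious
  feature–label association, and the fold-mean AUROC concentrates away
  from chance.

## Synthetic study conditions

The generator emulates the aspects of IMC data the pipeline relies on, at a
scale that trains on one CPU in minutes: 20 samples per class, 128×128
images, 5 marker channels, 40 cells of 3 types (13 A, 13 B, 14 C) rendered
as Gaussian blobs (σ = radius/2, truncated at the radius) with Poisson
counting noise (30 photons per unit intensity) and additive Gaussian noise.
Type C is multi-lobed so irregularity selection has genuine shape contrast.
Class 1 plants eight A–B pairs within 6 px of each other — a pervasive
co-occurrence difference, as microenvironment shifts in real tissue are —
while class 0 keeps every A–B pair at least 18 px apart; cell counts and
marker signatures are identical between classes, so spatial arrangement is
the only discriminative signal. Ground truth (type maps, cell centres,
signal-region boxes) is returned for validation.

What the generator does **not** emulate: real marker panels and spillover,
acquisition artefacts (hot pixels, drift), cell-shape diversity beyond the
lobed type, within-class biological heterogeneity, and batch effects.
Passing the synthetic recovery checks therefore demonstrates that the
implementation learns and localises a planted spatial co-occurrence under
counting noise — not that it reaches any particular accuracy on clinical
cohorts.

## Desk-scale configuration

Tests and the acceptance script run a reduced configuration chosen for
single-CPU budgets: h = 32 crops, width 24, depth 3, d = 32, Q = 128,
40 epochs, lr 3e-3, 50 evaluation folds. The crop-selection and
featurisation constants (100 superpixels, M = 30, top-20 prioritisation,
K = 30 frequency clusters, k = 10 microenvironment clusters, top-25%
abundance rule) are the method's standard settings.

## Known limitations

- The irregularity metric (1 − extent) is the most direct reading of
  "deviation from a quadrilateral"; it is pluggable, and 1 − solidity is a
  natural alternative for masks with internal holes.
- Bag-global pooling of location probabilities is used (the bag conditions
  the prediction as a whole); per-crop-then-merge pooling is a plausible
  variant and would change gradient routing.
- Crop-level labels for the SHAP forest are inherited sample labels; most
  crops of a positive sample are not themselves informative, so crop-level
  probabilities are biased toward the class prior, which Σ|φ| importance
  inherits as a baseline.
- Co-occurrence counting is crop-level presence (types present together
  under one crop mask); distance-thresholded variants are not implemented.
- The evaluation classifier and split proportions (test fraction 0.3) are
  defaults, not tuned; multi-class outcomes are supported by the loss but
  untested beyond K = 2.
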