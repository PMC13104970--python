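# milniche

Segmentation-free multiple-instance learning for discovering
outcome-associated immune microenvironments in multiplexed tissue images.

Spatial proteomics modalities such as imaging mass cytometry (IMC) measure
dozens of protein markers per pixel across a tissue section. Linking the
spatial organisation of immune cells in these images to clinical outcomes
usually starts with single-cell segmentation, which fails for cells with
complex morphologies (microglia, neurons, astrocytes). `milniche` instead
treats each sample's image as a *bag* of automatically selected region crops
and learns, end to end, which local microenvironments predict a binary
outcome — without segmenting a single cell. It then explains its predictions
by painting an importance map over the tissue and featurises samples for
downstream classifiers and survival stratification.

## The method

1. **Informative-crop selection.** Each image is partitioned into 100 SLIC
   superpixels. Shape irregularity of a superpixel mask is scored as
   `1 − extent` (one minus the fill fraction of its bounding box); the
   M = 30 most irregular superpixels — those straddling dense, heterogeneous
   cellular regions rather than empty background — become the sample's
   instances. Each instance is the margin-expanded bounding-box crop,
   resampled to h×h×N, together with its binary membership mask.

2. **Quantile-aggregated instance scoring.** A small fully convolutional
   network produces per-location class probabilities P ∈ R^{h′×h′×K} for
   every crop. For each class k the mask-filtered probabilities of the whole
   bag are pooled and sorted into a vector 𝒫̃_k, and summarised by Q order
   statistics taken at rank index ⌈|𝒫̃_k| · (q − ½)/Q⌉ for q = 1..Q. The
   per-class quantile vectors are concatenated into V ∈ R^{K·Q} and mapped
   through a trained linear readout and softmax to the sample-level class
   probabilities S. Training minimises categorical cross-entropy
   ℒ = −(1/I) Σᵢ Σₖ y_{ik} log S_{ik}; gradients flow through the selected
   order-statistic values into the network.

3. **SHAP prioritisation.** Each crop's embedding X ∈ R^d (mask-averaged
   penultimate feature map) is scored by a random forest trained on crop
   embeddings with inherited sample labels. Exact path-dependent tree-SHAP
   attributions φ over the d dimensions are summarised as
   Importance = Σⱼ |φⱼ|, painted back over the prioritised superpixels as an
   image-resolution importance map.

4. **Featurisation and evaluation.** Per sample, either the mean embedding
   of the top-20 SHAP-ranked crops (MI features, length d) or the fraction
   of its crops in each global k-means embedding cluster (frequency
   features, K = 30). A random-forest classifier over repeated random folds
   (donor-grouped, label-stratified; 200 folds by default) reports the mean
   and standard deviation of the AUROC. Crop embeddings can further be
   clustered into k = 10 prototypical microenvironments and samples
   stratified into top-25% high/low abundance groups per cluster.

Because no public IMC cohort ships with the package, a first-class
synthetic-data module generates IMC-like images — sparse marker-expressing
cell blobs of three types on low background with Poisson counting noise —
in which the positive class plants adjacent A–B cell pairs while the
negative class keeps the same cell types far apart. Ground-truth type maps
and signal-region boxes make every stage of the pipeline testable.

## Worked example

```python
import milniche as mn

ds = mn.generate(mn.SyntheticConfig(seed=0))              # 2 x 20 samples
cfg = mn.toy_run_config(seed=0, n_folds=50)               # desk-scale network
result = mn.run_pipeline(ds.images, ds.records, cfg)

ev = result.evaluation
print(f"mean AUROC {ev.mean_auroc:.3f} +/- {ev.std_auroc:.3f}")
print(f"final training loss {result.loss_history[-1]:.3f}")
```

prints (about two and a half minutes on one CPU):

```
mean AUROC 1.000 +/- 0.000
final training loss 0.007
```

The held-out samples are perfectly separated because the planted A–B
adjacency is the only difference between the classes, and the learned
importance maps concentrate more than twice the expected mass inside the
planted signal regions (`mn.signal_overlap` against
`ds.signal_regions`). The same entry points are available from the shell:

```bash
milniche simulate --out data/ --seed 0
milniche run --manifest data/manifest.csv --out runs/toy --toy --seed 0
```

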