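# Methods

## The model

`angiodl` implements an interpretable framework for scoring tumor
angiogenesis directly from H&E histology. The core is a three-arm network
with one shared convolutional encoder:

* **Mask arm** — an encoder-decoder with a skip connection that predicts a
  two-class (vessel / non-vessel) probability map `P^Mask` per pixel. Its
  thresholded output is the interpretable product: a vascular mask standing
  in for CD31 immunostaining.
* **Angio arm** — further convolutions on the encoder bottleneck, global
  average pooling, and a linear readout giving one scalar score `P^Angio`
  per patch, supervised by the slide's RNA Angioscore.
* **Consistency arm** — a function of the mask output only: the global
  average of the positive-class probability map (the fractional positive
  activation) passed through a small learnt scalar nonlinearity (1 → 2
  hidden tanh units → 1) to predict the same RNA score, `P^Cons`. This arm
  ties the two supervision signals together: the mask the network draws must
  explain the score it predicts.

Supervision is *dual ground truth*: no patch carries both label types.

* RNA batches: 32 patches from exactly 4 distinct slides, 8 patches each
  (sampling several slides per batch also stabilizes shared-feature
  statistics). Loss: the batch MSE of slide-averaged predictions,

  `L_RNA = (1/N) Σ_slides [(T − mean P^Angio)² + (T − mean P^Cons)²]`,

  with `T` the slide's RNA Angioscore and `N` the slides in the batch.
* Mask batches: 4 patches with binary vessel masks. Loss:
  `L_Seg = 0.9·Dice + 0.1·WCCE` plus `L_Cons = MSE(P^Angio, P^Cons)`.

The Dice term is soft Dice with additive smoothing 1.0 in numerator and
denominator, computed per class over the pooled batch and averaged over the
two classes; WCCE is class-weighted categorical cross-entropy from
probabilities (clip ε = 1e-7), with weights defaulting to inverse
class-pixel frequency on the training pairs, renormalized to mean 1. All
three losses are pinned to independent brute-force evaluations of their
formulas at 1e-6 in the acceptance suite.

The consistency pooling uses the *soft* probability map during training —
pooling a hard binarized mask would not be differentiable — and the hard
0.5-thresholded fraction only at inference. The consistency head is
initialized near the identity map with positive slopes so it is
monotone-capable from the first step; its permutation invariance (it sees
only the spatial mean) and monotonicity in uniform probability shifts are
tested properties.

### Network implementation

The network, its losses and the optimizers are implemented directly over
NumPy with an in-package reverse-mode autodiff (`angiodl.autograd`):
broadcast-aware arithmetic, im2col convolution, max pooling, nearest
upsampling and stable softmax, with gradient correctness pinned by central
finite differences. This keeps the framework dependency-light, fully
deterministic on one CPU, and fast enough at desk scale. The encoder is a
configurable-width conv encoder (profiles `small` = 8 and `base` = 16 base
channels, one 2× pooling level); `pretrained_encoder` is accepted in the
config for interface parity but initialization is always random, so no test
ever needs a weight download.

### Training schedule

Stage 1 pre-trains the mask arm alone (segmentation loss, Adam). Stage 2
trains all arms on alternating RNA and mask batches (ratio 1:1,
configurable) with gradient descent + momentum 0.9, checkpointing every
epoch. Two guards protect the pretrained mask arm from the initial shock of
the untrained score heads, whose DC error gradient otherwise drives the
shared encoder coherently away from its pretrained features (observed as a
collapse of segmentation precision or recall within one epoch at some
seeds): the angio head's output bias starts at the mean training target,
and the first mixed epoch trains only the angio/consistency heads before
the whole network is unfrozen (both configurable). Relatedly, the
consistency arm's pooled activation is treated as a constant during
backpropagation (`cons_stop_gradient`, default on): the RNA loss trains the
head's scalar nonlinearity but cannot push the mask probabilities toward
the score scale; the mask stays shaped by its own supervision while the
consistency tie is still enforced on the scalar outputs. This matches the
reading of the consistency arm as consuming the mask arm's *output* rather
than co-training it. the deployed checkpoint maximizes Spearman correlation between
validation slide scores and their targets (ties → earliest epoch; constant
predictions score −1). An epoch of mixed training is one pass over the RNA
patch inventory. Batches are never mixed across ground-truth kinds within a
step. The full-scale defaults are 10 + 10 epochs at learning rate 1e-4; the
desk-scale profile (`angiodl.experiments`) trains the reduced encoder from
random initialization in 3 + 5 epochs, which wants larger steps — 1e-2
(Adam, stage 1) and 1e-3 (SGD, stage 2); 1e-2 in stage 2 was observed to
destabilize the pretrained mask arm.

### Scores

A patch's score is `100 × fraction of pixels with P(vessel) > 0.5`
(threshold configurable); a slide's **H&E DL Angioscore** is the mean over
its patches (1500 patches per whole slide at full scale; 250/1000 for local
regions). Heatmaps average percent-positive patch scores over a 416 px grid,
with no-data cells flagged as NaN and excluded from color scaling.

## RNA Angioscore

For a genes × samples expression table: FPKM → TPM by per-sample
renormalization to a column sum of 10⁶ (scale-invariant per sample; an
all-zero sample is an error), then `log(x+1)` elementwise, then the mean
over the six angiogenesis signature genes VEGFA, KDR, ESM1, PECAM1, ANGPTL4,
CD34. The natural log is used; the log base does not affect any rank-based
result but is fixed for reproducibility. Gene matching is exact
(optionally after uppercasing); aliases are out of scope.

## Ground-truth construction from paired H&E/IHC

Corresponding patch pairs (512 px by default) are registered on their shared
hematoxylin concentration channel: optical-density deconvolution
(`OD = −log((I+1)/256)`, Ruifrok-Johnston stain vectors, H&E basis for H&E,
H-DAB for IHC), a phase-correlation translation seed (pure gradient descent
has a small capture range on sparse vascular content), then affine and
B-spline stages maximizing intensity correlation over a 3-level pyramid
(SimpleITK). The identity transform is always a candidate, so registration
never worsens the similarity metric; a pair whose best similarity does not
exceed the pre-registration value by the configured margin (default 0) is
flagged failed and excluded. A 416 px center crop removes warp edge
effects. Whole-slide mosaicking and the initial slide-level rigid alignment
are out of scope: the pipeline accepts pre-cut corresponding patch pairs.

IHC is converted to a vascular mask by a deterministic 3-class classifier:
DAB concentration > 0.25 marks candidate staining; connected components
that are solid *and* round (solidity ≥ 0.85 and eccentricity ≤ 0.92, or
solidity ≥ 0.75 with eccentricity ≤ 0.6 to catch very round blobs with
threshold holes) are non-specific artifacts, everything else CD31-positive.
Artifacts are treated exactly like negative staining in the final binary
mask. This replaces a learned annotator-trained classifier with the same
3-class contract; the morphology rule exploits the fact that vessels are
elongated or branched while non-specific droplets are compact.

Train/eval splitting of pairs is always by slide, never by patch.

## Color operations

* **Normalization**: Reinhard mean/sd matching per channel in Lab space,
  reference statistics pooled from training images. Constant-color input
  (zero variance) is returned unchanged with a warning. The method is
  pluggable behind this contract.
* **Augmentation**: mirror drawn uniformly over {identity, horizontal,
  vertical, both}; per-channel multiplicative jitter of HED concentrations
  in (0.975, 1.025) applied in deconvolved space and recomposed; a random
  saturation multiplier in [0, 0.5] emulating faded slides. Degenerate draws
  (multiplier exactly 1) skip their stage so identity parameters are the
  exact identity.
* **Magnification**: the model works at ~0.5 µm/px; 40X (~0.25 µm/px) input
  is area-downsampled by 2, anything else is refused.
* **Patch sampling**: uniform over all anchor positions whose full patch
  lies inside the region mask (window sums via 2-D cumulative sums);
  count = min(n_target, ⌊cap·region_area/patch_area⌋) with cap 3× coverage
  by default. Coordinates are 0-based, top-left anchored, half-open,
  reported as (x, y, w, h).

## Survival machinery

Cox proportional-hazards fits use the partial likelihood with Efron tie
handling (lifelines), reporting the high-vs-low hazard ratio with Wald 95%
CI; group comparison uses the two-sided log-rank test, concordance is
Harrell's c over usable pairs (orientation: higher score → longer survival
gives c > 0.5). The threshold scan sweeps ≥20 cutoffs over the interior
(10th–90th percentile) score quantiles, recording log-rank p and HR per
cutoff; candidate stratification thresholds are local minima of p detected
on the −log₁₀ p trace with a minimum prominence of 0.25 decades (grid
endpoints eligible). The scan is exploratory and its p-values are
deliberately unadjusted — it mirrors how stratification cutoffs are chosen
on an independent cohort and then applied elsewhere (two-threshold
three-class stratification and median splits are both supported; thresholds
are always inputs, never hard-coded).

## Synthetic fixtures: what they emulate and what they do not

The generator plants every quantity the pipeline is later asked to recover:

* **Vessel patches** — branching random-walk strokes of varying width with
  a pale, eosin-poor lumen and a mauve endothelial rim on a pink textured
  background with scattered nuclei. Stroke placement iterates until the mask
  fraction is within ±0.03 of target (strokes taper near the target; a
  handful of regeneration attempts absorbs rare overshoots at small sizes).
  `vessel_fraction` is exactly `mask.mean()`; all generators are
  byte-deterministic under a fixed seed.
* **Slides** — patches whose fractions jitter around a slide fraction; the
  slide score is `g(f) = a·log(1 + b·f)` (defaults a=1, b=10, strictly
  increasing) of the realized mean fraction, plus optional Gaussian noise.
* **IHC pairs** — DAB-brown vessels over a hematoxylin counterstain that
  reuses the H&E patch's nucleus layout (the shared structure registration
  needs), plus isolated round non-specific brown blobs (label 2) planted
  away from vessels until their pixel fraction matches the artifact rate,
  and an optional affine warp whose true parameters are returned.
* **Expression** — six signature genes whose FPKM increases strictly with
  the slide's vessel fraction over fraction-independent housekeeping genes,
  so the computed Angioscore ranks samples exactly by vascularity at zero
  noise.
* **Survival** — proportional hazards `h(t|s) = h₀·exp(−β·s)` (higher score,
  better survival) with exponential times (Weibull optional) and
  independent uniform censoring calibrated to the requested censor rate.

What the fixtures do *not* emulate: real histologic texture and nuclear
morphology, stain variability across labs, tissue folds and pen marks, the
continuum of vessel calibers, or biologically realistic expression
covariance. Passing the desk-scale studies therefore demonstrates that the
algorithms are implemented correctly and can recover known structure — not
that the small network would segment real CD31 vasculature.

## Desk-scale studies (angiodl.experiments)

Problem sizes are chosen to run the whole suite on one CPU in a few
minutes:

* **Parameter recovery** — 30 slides × 8 patches at 128 px, vessel fractions
  0.01–0.3, score noise sd 0.02; slide-level split 18/4/8
  (train/validation/test); 3 pretraining + 5 mixed epochs. Checks: held-out
  slide scores vs true scores Spearman ≥ 0.8, mask F1 ≥ 0.6 vs planted
  masks, and mask-arm vs consistency-arm slide readouts Spearman ≥ 0.9.
* **Registration recovery** — 20 pairs at 192 px with planted translations
  up to 8 px, rotations up to 2°, scale within 2%; mean residual
  displacement of the recovered transform against the planted warp's
  inverse, on a central grid.
* **Survival recovery** — planted two-group HR of 2.0 at n=500 (recovered
  within [1.6, 2.5]); a planted score boundary between two bounded-support
  populations localized by the scan (nearest detected p-minimum within one
  grid step of the set of thresholds realizing the planted partition —
  bounded support matters: with Gaussian clusters the log-rank-optimal
  cutoff is a cube-root-consistent estimator that chases tail stragglers,
  so a point boundary is not statistically identifiable at this cohort
  size); and the null c-index at n=1000 (0.5 ± 0.03).

## Numerical choices and degenerate inputs

* float32 for training; losses evaluated on float64 inputs stay float64, so
  oracle comparisons are at full precision.
* Dice smoothing 1.0; cross-entropy clip 1e-7; softmax via max-shifted
  exponentials.
* Checkpoint-selection ties break to the earliest epoch; undefined
  (constant-prediction) Spearman scores as −1.
* All-zero expression samples, constant vectors in rank correlations,
  single-class AUC inputs, empty survival strata and all-negative truth
  masks raise errors rather than returning silent defaults; empty patch
  sampling regions warn and return empty.
* Seeds: every stochastic component takes an explicit seed or
  `numpy.random.Generator`; identical seeds give identical results
  (byte-identical for images).

## Known limitations

* The encoder is deliberately small; no pretrained backbone is bundled.
* The IHC artifact classifier is a morphology heuristic tuned to the
  synthetic artifact model (isolated compact blobs); heavily confluent
  non-specific staining would need the learned-classifier route.
* Registration assumes the pair is already coarsely corresponding (the
  slide-level manual alignment step is out of scope).
* The threshold scan reports unadjusted p-values by design; its output is a
  candidate set of cutoffs to validate on independent data, not a
  hypothesis test.
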