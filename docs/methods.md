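# Methods

## Model

The classifier combines three ideas: a four-scale feature pyramid from a
residual backbone, orderless texture encoding at every scale, and deep
supervision of the per-scale classifiers.

**Backbone.** A 224×224 (or any multiple of 32) grayscale patch passes a
stem convolution and four residual stages whose outputs halve spatially
(224 → 56/28/14/7). Two profiles share this contract:

| profile | blocks | stage widths | purpose |
|---|---|---|---|
| `reference` | bottleneck, 3/4/23/3 (101-layer layout) | 256/512/1024/2048 | the clinical-scale configuration |
| `test` | basic, 1/1/1/1, stride-4 stem | 8/16/32/64 | CPU-scale training and CI |

No pretrained weights are used; initialisation is He-normal for
convolutions, deterministic per configured seed.

**Texture encoding.** Each stage output is projected by a 1×1 conv +
batch-norm + ReLU block to D channels and read as N = H·W descriptors.
A dictionary of K textons with per-texton smoothing factors soft-assigns
every descriptor (softmax over −s_k‖x_i−c_k‖², computed max-subtracted
for stability) and aggregates assignment-weighted residuals into a K·D
vector. The aggregation sums over spatial positions, so the feature is
permutation-invariant — it represents texture statistics, not layout.
Defaults K = 32, D = 128 (the reference setting); the test profile uses
K = 8, D = 32 to match its narrow backbone. Codewords initialise uniform
in (−1/√K, 1/√K), smoothing factors uniform in (0, 1]; both are learned.
No further normalisation is applied inside the encoding block — the
classifier's L2 step provides the scale control.

**Classification and loss.** Per scale: L2-normalise the texture vector,
apply a fully connected layer. The four logit vectors are summed
element-wise (pre-softmax — summing logits rather than probabilities is
the natural reading of element-wise fusion into a softmax) and softmaxed.
The training objective is the unweighted sum of the four auxiliary
cross-entropies and the main cross-entropy on the fused logits, each
against the same label-smoothed target y_i = (1−ε)·1[i=true] + ε/C with
ε = 0.1. The relative scale weighting is emergent from joint convergence;
no explicit loss coefficients are used. Binary verdicts derive from the
five-class model by mapping {HSIL, CC} to positive; a two-class training
mode exists but is not the default.

**Ablation switches** reproduce the structural baselines: single-scale
encoding only (`use_pyramid=False`), pyramid without encoding
(`use_encoding=False`, global average pooling per scale), and main-loss
only (`deep_supervision=False`).

## Training recipe

Batch 16, 30 epochs, SGD momentum 0.9, initial lr 0.005 annealed per
batch with cosine to 0 (floor 0, no restarts), label smoothing 0.1,
no weight decay (configurable). Class imbalance is handled by weighted
random oversampling: each patch draws with probability proportional to
1/(its class count), with replacement, epoch length equal to the dataset
size — expected class frequencies are uniform. Augmentation: horizontal
and vertical flips, additive Gaussian noise (σ = 2% of the dynamic
range) and multiplicative brightness jitter in [0.8, 1.2], each applied
with probability 0.5. z-score statistics are global over the training
split (per-image normalisation is available but not default).
Cross-validation splits are grouped by patient identifier so no patient
appears in both train and test; fold sizes differ by at most one
patient. Model selection across folds is left to the caller (the
criterion is exposed, not hard-coded).

## Aggregation to volumes and patients

Patch risk ρ = P(HSIL) + P(CC); high-risk means ρ ≥ τ with τ = 0.8
(inclusive). A cross centre is a high-risk patch with at least
`arm_length` consecutive high-risk patches along the in-frame (window)
axis and along the cross-frame axis, counted over both sides of the
centre; grid borders simply terminate runs. `arm_length = 1` — one
in-frame and one cross-frame neighbour — is the default; the exact
minimum run length of the original rule is not published, so it is a
config parameter. A volume is positive iff a centre exists; a patient is
positive iff any volume is. The rule is monotone both in τ (larger
threshold, fewer positives) and in the patch scores.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV
TN/(TN+FN), accuracy (TP+TN)/N, F1 = harmonic mean of sensitivity and
PPV. Metrics with zero denominators are reported as missing, never
coerced to 0 or 1. All CIs are exact Clopper–Pearson intervals from beta
quantiles; F1 is treated as the pseudo-count proportion
2TP/(2TP+FP+FN), which makes its exact interval well-defined and
reproduces published interval widths. AUC is the rank statistic
U/(n₁n₂) (ties counted half); the Mann–Whitney test uses exact
enumeration for ≤ 8 observations per group without ties and the
tie-corrected normal approximation otherwise. On the 42/10/9/44 worked
example the accuracy computes to 81.90%, which we report as such (a
published rendering of the same matrix prints 81.91%); similarly an F1
that is not the harmonic mean of its printed companions is a rounding
artefact we do not chase — the formulas are authoritative here.

## Synthetic data: what it emulates and what it does not

Each synthetic volume renders a per-class texture motif on every frame:

- **MI** — horizontal sinusoidal layering (period 24 px, base 120,
  amplitude 50 on the 0–255 scale) plus a bright thin basement-membrane
  band at 62% depth;
- **CY** — the layered motif with 3–6 dark elliptical voids;
- **EP** — bright-fringed papillary undulations (column-dependent layer
  phase, amplitude 14 px, period 48 px);
- **HSIL** — a contiguous de-stratified homogeneous region (intensity
  140) replacing the layers;
- **CC** — a de-stratified region with alternating light/dark vertical
  attenuation bands (period 32 px).

Additive Gaussian noise (σ = 8, i.e. 8/255 of full scale) clipped to
[0, 255] stands in for OCT speckle. Lesions are placed as uniformly
random contiguous blocks spanning at least 3 frames and 3 full windows,
so the cross-shaped rule can always fire on a true positive; the
footprint is recorded in a per-(frame, column) mask. Patch labelling is
purity-constrained: on positive volumes only windows with ≥ 50% mask
coverage keep the positive label, the rest are excluded.

A fixed texture statistic — the lag-24 autocorrelation of mean-centred
column profiles ("layering statistic") — separates layered from
de-stratified tissue; with the default motifs, negative classes score
≥ 0.31 and lesion regions ≤ 0.0. The decision threshold 0.15 and the
CC-vs-MI separation margin 0.3 were calibrated once on 20 seeded volumes
per class and then frozen.

The generator does **not** model coherent speckle statistics, the
point-spread function, probe geometry, depth-dependent attenuation
beyond the motifs, imaging artefacts or defective volumes. Passing the
synthetic study therefore demonstrates that the implementation learns
and aggregates class-conditional texture correctly — not that the model
reaches clinical accuracy on real OCT, which requires the (non-public)
clinical datasets.

## Desk-scale fixture

The end-to-end checks use 30 patients (4 each of MI/CY/EP, 9 each of
HSIL/CC; one 10-frame 128×384 volume per patient, window 128, stride
64), giving ≥ 200 patches per class at ~1,300 patches total, split 75/25
by patient. The test-profile network trains at the native 128-px window
resolution for the full 30-epoch recipe; three seeds take a few minutes
each on one CPU. The reference profile is exercised for its shape
contract and forward pass, not trained at desk scale.

## Numerical choices

- Gradients come from a minimal reverse-mode tape over numpy
  (`octex.autograd`); convolution is im2col/col2im with BLAS GEMMs,
  batch-norm uses the closed-form backward through the batch statistics.
  Every primitive is verified against central finite differences.
- Softmaxes (assignment, fusion, loss) are max-subtracted; cross-entropy
  floors probabilities at 1e-12; fusion ties resolve to the lowest class
  index (argmax convention).
- Bilinear interpolation for patch resizing and heatmap upsampling;
  Grad-CAM hooks each backbone stage output (before encoding, which
  discards spatial layout), weights channels by spatially averaged
  gradients of the fused target logit, rectifies and max-normalises;
  overlays alpha-blend at 0.4 with the jet colormap.
- Determinism: every stochastic component (generator, sampler,
  augmentation, initialisation) draws from an explicit integer seed;
  single-threaded numpy makes runs bit-reproducible.

## Known limitations

- The reference (101-layer) profile is impractical to *train* without a
  GPU; it is instantiated and forward-checked only.
- Synthetic motifs are far easier than clinical OCT; accuracy numbers on
  them say nothing about clinical performance.
- The voting rule's "consecutive" run length and the original patch
  extraction stride are configurable guesses where the source protocol
  is unpublished.
- F1 confidence intervals via pseudo-counts are exact for the proportion
  they describe but are not a general-purpose F1 interval.
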