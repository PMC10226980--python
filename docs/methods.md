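# Methods

## Problem setting

Widefield OCTA en face images show diabetic-retinopathy lesions — capillary
dropout (ischemic areas), abnormal tortuous vessels, bright dot lesions —
only in small, scattered portions of a very large image, and clinical
datasets typically carry only a patient-level label (diabetic / healthy).
`milenface` implements an instance-space multiple-instance-learning (MIL)
classifier for this setting. A whole image is a *bag* with label
Y ∈ {0, 1}; a regular g×g grid of sub-patches are its *instances*
x₁…x_k (k = g²), each inheriting Y. Under the standard multiple-instance
(SMI) assumption, lesion-bearing instances occur only in positive bags, so
the inherited instance labels are noisy only on positive bags — asymmetric
label noise.

## Pipeline

1. **Pre-processing.** Gaussian denoising (σ = 1, reflect boundary —
   chosen so the border is not darkened, which would mimic ischemia), then
   an affine rescale of the whole image to mean 0, standard deviation 1.
   Constant images are rejected rather than silently zeroed.
2. **Bag decomposition.** The image is cut into g² equal instances in a
   checkerboard manner, row-major order, from a centered crop when the side
   is not divisible by g (2044×2048 at g = 10 → 100 instances of 204×204,
   crop offset (2, 4); the symmetric crop spreads the information loss over
   both borders). `stitch_instances` is the exact inverse on the crop and
   flags uncovered border pixels.
3. **Instance classifier.** A compact residual CNN: stem convolution, four
   blocks of three 3×3 convolutions (SeLU after every convolution, identity
   skip — 1×1 projection on channel change — and 2×2 average pooling), then
   global average pooling and a single-unit affine head. Output is an
   unbounded real score (a logit); the sigmoid lives only inside the losses.
   There is no batch-coupled normalization anywhere, so an instance's score
   depends on that instance alone (SeLU is self-normalizing). Initialization
   is LeCun-normal, seeded. Default widths are 8 / (12, 16, 24, 32)
   (≈ 59k parameters), sized for single-core CPU training on the phantom
   study; widths are config-exposed.
4. **Training.** All training instances are shuffled across bags — the
   network never sees bag affiliation — augmented (quarter-rotations,
   brightness shift U(−0.1, 0.1) and contrast scale U(0.9, 1.1) in
   standardized units, applied after standardization), and optimized with
   Adam on weighted binary cross entropy of instance logits against
   inherited labels. Healthy instances are weighted 2× — positive bags carry
   label noise, negative bags do not, so trusting healthy instances more
   suppresses false positives. After each epoch the validation bags are
   scored, instance scores are max-pooled, and the bag-level ROC AUC
   (AUC_MIL) decides model selection: the weights of the best epoch are
   kept, with early stopping after `patience` epochs without improvement.
5. **Bag decision.** The deployed bag score is the mean of the three highest
   instance scores (top-k pooling, k = 3): a robustified max that a single
   outlier instance cannot dominate. The operating threshold maximizes the
   geometric mean √(TPR·(1−FPR)) over all ROC operating points of the
   validation bag scores (candidates: midpoints between consecutive distinct
   scores plus sentinels beyond the extremes; ties break toward the higher
   threshold, i.e. fewer positive calls). Decisions are `score > threshold`.
6. **Explanation.** Grad-CAM per instance at the final convolution before
   global average pooling: channel weights are the spatial means of
   ∂score/∂A_c, the map is ReLU(Σ_c w_c A_c), bilinearly upsampled to the
   instance. Maps of one bag are min-max normalized jointly (a per-instance
   mode exists) so the stitched overlay is comparable across the image.
7. **Robustness.** FGSM: x_adv = x + ε·sign(∇_x L(Θ, x, y)) with ε = 0.1 in
   standardized units, sign(0) = 0. Each instance is attacked independently
   through the instance loss under its inherited label (a pooled-loss attack
   through the top-k bag score is a config switch); no clipping by default,
   since standardized inputs are unbounded.

## Loss functions

The default loss is applied directly to instance predictions (full binary
cross entropy — both class terms — since a positive-term-only form would
ignore healthy bags entirely), accepting label noise in exchange for the
k-fold increase in training data. The pre-pooling comparison loss
(`prepool_loss`), which applies BCE to the pooled bag logit and thereby
removes the label noise, is provided as an alternative mode, not the
default.

Two pooling operators coexist deliberately: model selection uses **max**
pooling inside AUC_MIL, while the deployed decision uses **top-3 mean**;
both are config switches (`early_stop_pooling`, `pooling`).

## Evaluation metrics

`evaluate` reports bag ROC AUC, AUC_MIL, F1 = 2TP/(2TP+FP+FN), plain and
"corrected" accuracy/precision, instance accuracy/precision against
inherited labels, and the confusion counts. *Corrected* metrics do not
penalize a negative decision on a diabetic bag with no visible signs
(severity `no_signs`): such bags, when predicted negative, move from the
false negatives to the true negatives for the accuracy computation;
precision remains TP/(TP+FP) on the corrected table. The verbal definition
of these corrections admits more than one arithmetic; this re-assignment
rule is the package's reading and is exercised in the tests. Instance
decisions use the same operating threshold as bags, so instance and bag
metrics share one decision rule.

Because positive bags contain mostly lesion-free instances, a *low*
instance accuracy together with a *high* bag AUC is the expected signature
of a sound fit; a high instance accuracy would indicate overfitting to the
label noise.

## Synthetic phantom study

No public OCTA dataset with this structure exists, so the package ships a
phantom generator that reproduces the *label structure* rather than OCTA
physics: dark gamma-speckle floor, a capillary-scale ridge mesh (filaments
along zero crossings of smoothed noise), a bright branching vessel tree
grown by biased random walks from an optic-nerve-head disc, and a darker
foveal spot. Lesions — ischemic ellipses that attenuate the signal to the
background floor, short high-tortuosity bright segments with oscillating
width, and clusters of small bright dots — are planted only in positive
bags, only inside a randomly chosen subset of grid cells (fraction
U(0.08, 0.35)), and every altered pixel is recorded in a ground-truth mask.
15% of positive bags receive no lesion at all, mirroring the
diabetic-without-visible-signs subgroup; severity tags follow the affected
cell count (0 → `no_signs`, ≤ 3 → `mild`, else `severe`).

Default study conditions keep the clinical class ratios at desk scale:
384×384 images on a 6×6 grid (64×64 instances), train 60 diabetic / 18
healthy (the clinical 211:64 ratio at ~80 bags), validation 12/12 and test
11/4 (the clinical 24/24 and 22:8 halved). The full 2044×2048 / 10×10
geometry is reachable through the same config. These phantoms deliberately
omit OCTA speckle statistics, projection artifacts and segmentation errors;
passing the synthetic study demonstrates that the *pipeline machinery*
(bagging, noisy-label training, pooling, thresholding, explanation, attack)
behaves as designed, not that clinical-grade accuracy transfers to real
scans.

## Numerical choices

- The neural-network engine is a small numpy autodiff core written for this
  package (stride-1 convolutions as sums of shifted GEMMs, exact backward
  passes verified against finite differences in the tests); float32
  throughout training, float64 for scores and metrics.
- Optimizer Adam (lr 1e-3, β = 0.9/0.999), batch 32 instances, epoch cap 8
  for the desk-scale study with patience 10 — bag-AUC model selection
  saturates within 8 epochs at this scale, and the ~700 optimizer steps this
  yields are what the 78-bag phantom study needs to converge on one CPU core
  (larger batches halve the step count and visibly under-fit under label
  noise).
- AUC uses the Mann–Whitney half-credit tie convention (scikit-learn's
  `roc_auc_score`).
- Degenerate inputs: constant images raise; empty score lists raise;
  single-class label sets raise before any AUC/threshold computation;
  all-equal scores select a sentinel threshold with gmean 0.
- FGSM bound: ε is applied in float32, so the max-norm bound is attained at
  float32(ε) exactly.
- Severity thresholds (mild ≤ 3 cells) and augmentation magnitudes
  (b = c = 0.1) are package choices where the method names the operation but
  not the magnitude.

## Known limitations

- The parameter totals reported for the original clinical deployment of
  this architecture family (443,489 for the instance classifier; 1,660,993
  for its whole-image twin) do not pin down the layer widths — the two
  totals even disagree for architectures described as identical — so the
  builder exposes widths instead of hard-coding a guess. The VGG16
  benchmark totals *are* architecture-forced and reproduced exactly.
- ImageNet weights for the VGG16 benchmark are not bundled; the builder
  constructs the exact architecture and trainable-flag layout with seeded
  random initialization, and pretrained weights can be loaded into
  `params` when available.
- Clinical-scale training (2044×2048, hundreds of bags) is out of reach of
  the numpy engine in reasonable time; the package targets the desk-scale
  phantom study and correctness of every primitive.
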