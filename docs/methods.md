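# Methods

This note documents the models implemented in `iopscreen`, the phantom
generator that serves as the package's data substrate, the numerical
choices, and what the test suite does and does not establish.

## 1. The phantom cohort

### Clinical records

Each sample carries eight attributes: age (years), pupil-center thickness
and corneal-vertex thickness (µm), corneal volume (mm³), anterior chamber
depth (mm), anterior chamber volume (mm³), corneal diameter (mm) and IOP
(mmHg). Records are drawn from a two-component multivariate Gaussian:
the class (high-IOP with probability 100/780 ≈ 12.8%) selects the mean
vector, and a shared within-class covariance supplies the noise. The
default class-conditional means reproduce the baseline table of the
emulated cohort verbatim — including its physiologically odd entries
(chamber depth 7.9 mm normal vs 2.5 mm high; corneal diameter ≈ 3 mm).
These are deliberately not reinterpreted; they are configuration values.

Labels follow the 21 mmHg rule exactly: IOP is drawn as a truncated normal
within each class (rejection sampling). With the default IOP sd of
2.2 mmHg the threshold sits ≈ 2.7 sd from both class means, so truncation
shifts class means by less than one standard error at n = 10 000.

### Correlation calibration

The correlations the cohort must reproduce are *cohort-level* Pearson
coefficients: r = 0.41 between central thickness and IOP, −0.17 for
chamber depth, −0.14 for chamber volume. For a two-component mixture with
class prevalence p, between-class mean gaps Δa, Δi and shared within-class
sds σa, σi, the pooled covariance decomposes as

    cov_pooled = ρ_w σa σi + p(1−p) Δa Δi,
    var_pooled(x) = σx² + p(1−p) Δx².

`PhantomConfig` inverts this for the within-class correlation ρ_w per
targeted attribute at construction time; an infeasible solve (|ρ_w| ≥ 1)
or a non-PSD correlation matrix raises a configuration error.

Default sds are 10% of the pooled attribute mean, with two exceptions:
anterior chamber depth (2.8 mm) and IOP (2.2 mmHg). The published chamber
depth class gap is so large relative to a 10% sd that the mean-gap term
alone drives the pooled correlation to ≈ −0.86 — no within-class
correlation could recover −0.17. The widened pair is the smallest round
combination that makes the solve feasible with margin. A consequence worth
knowing: the within-class chamber-depth–IOP correlation comes out strongly
*positive* (≈ +0.76) while the cohort-level correlation is negative — a
Simpson-style construction forced by the printed class means.

Measured calibration at n = 10 000 (five seeds): thickness r = 0.409 ± 0.008,
chamber depth −0.191 ± 0.012, chamber volume −0.148 ± 0.019. The ≈ 0.02
negative bias on chamber depth comes from the IOP truncation interacting
with the positive within-class correlation; it stays well inside the
±0.05 acceptance band and is left uncorrected.

### Images

Rendering is a pure function of (record, config, seed). A bright corneal
band (intensity 0.90) follows a shallow parabolic arc whose per-column
integer thickness is an affine map of pupil-center thickness
(t ≈ 2 + (CCT − 430)/20 px at 64 px); a dark wedge (0.08) below it has
vertical extent affine in chamber depth (d ≈ 2.2·ACD + 4 px); the rest is
mid-gray background (0.35). Additive Gaussian speckle (sd 0.05 by default)
is clipped to [0, 1]. All label-relevant signal therefore lives in the
band + wedge region, and the renderer returns the geometry so a boolean
informative-region mask can be constructed per image — the reference
surface for attribution checks. The default canvas is 64 px (tests and
desk-scale runs); 224 px matches the full backbone preset.

Artifact injection emulates the failure modes of generative augmentation:
band gaps (edge discontinuity), saturated patches, uniform texture-noise
patches, and Gaussian blur, each with a [0, 1] magnitude. Magnitude 0 is
the identity for every kind.

Synthetic patients own one or two same-class eyes (two with probability
0.871, matching the emulated 780 eyes / 417 patients ratio).

## 2. Quality control

The Broad Learning System maps inputs (images resampled to 32 × 32 and
flattened) through m random sigmoid feature nodes and p random sigmoid
enhancement nodes; only the output weights are learned, by ridge
regression over the concatenated [feature | enhancement] design (the
standard broad form; an `enhancement_only` switch restricts the design to
enhancement nodes). λ defaults to 1e-2; scores are clipped to [0, 1] so
the gate threshold T = 0.7 (boundary inclusive) is meaningful. Reference
node counts are 1000/600; desk-scale runs use 200/100.

Training targets are the normalized cross-correlation between a generated
image and its paired source, mapped to [0, 1] and scaled by (1 − artifact
magnitude) for deliberately corrupted samples — a cheap proxy that is
monotone in corruption severity. With corruption magnitudes drawn from
U(0.5, 0.95), clean targets sit at ≈ 1 and corrupted ones below ≈ 0.5,
so T = 0.7 separates them; a gate trained on 400 phantoms classifies a
disjoint 200-phantom set at ≥ 0.93 accuracy across seeds.

Incremental widening draws Δp new random enhancement nodes and refits the
output weights through the Schur complement of the widened ridge normal
equations, reusing the cached Cholesky factor — numerically identical
(≤ 1e-10 observed) to a full re-solve. Widening never increased training
MSE in any tested configuration; with λ > 0 this is an empirical property,
not a theorem (the penalized objective, not the MSE alone, is what
provably cannot increase).

The geometric screen is independent of the BLS: Canny edge presence,
connectivity of the thresholded corneal band (more than one major
connected component ⇒ discontinuity), and saturated-area counting
(> 1% of pixels at ≥ 0.99 ⇒ saturation; the clean band at 0.90 with
0.05 speckle stays safely below).

## 3. Backbone

A Swin-style hierarchical transformer: 4 × 4 patch embedding, four stages
of window-restricted multi-head self-attention alternating plain and
shifted windows (cyclic shift with the standard cross-boundary attention
mask, learnable relative position bias per window), MLP blocks with GELU,
LayerNorm throughout, and 2 × 2 patch merging between stages so spatial
sides halve and channels double. Head: LayerNorm → global average pool →
linear. A window larger than the stage grid falls back to global attention
over the grid — the documented behaviour of the late tiny-preset stages.

Presets: *full* (224 px, embed 96, depths (2, 2, 6, 2), heads
(3, 6, 12, 24), window 7) mirrors the reference configuration; *tiny*
(64 px, embed 24, depths (1, 1, 2, 1), window 4, MLP ratio 2) is the
default for tests and desk-scale runs. Stage grids at 64 px: 16, 8, 4, 2.

No external pretrained weights are shipped. `init` is either random or
*phantom-pretrain*: supervised domain classification on (quality-gated)
augmented phantoms, after which a freeze policy pins parameter subtrees by
name prefix (default: the patch embedding and stage 0, the closest
structural reading of "lower convolutional and shallow transformer
layers"). Frozen parameters are verifiably bit-identical across training.
Training uses cross-entropy, AdamW, and linear-warmup + cosine decay.

Feature extraction for fusion: GAP-pooled maps of the last two stages,
concatenated (stage selection is configurable; no selection criterion is
prescribed upstream, so this is a package default).

## 4. KAN fusion

Each KAN edge carries a learnable univariate function
φ(x) = Σₖ αₖ Bₖ(x) on a clamped uniform B-spline basis (degree 3, 16
basis functions on [−3, 3] by default; inputs are standardized so the
domain covers ≈ 3 sd, and out-of-domain inputs are clamped to the
boundary, where the input gradient is zero). An optional polynomial term
Σₘ βₘ xᵐ (off by default) covers global trends. Node outputs are
λ-weighted sums of edge functions — linear in all parameters, nonlinear in
x. The basis and its derivative are evaluated by an in-package Cox–de Boor
recursion (validated against an independent design-matrix oracle); both
enter a custom autodiff op so gradients flow to α, λ, β *and* the inputs.

Fusion head: the image embedding and the six standardized structural
clinical attributes (pupil-center thickness, vertex thickness, corneal
volume, chamber depth, chamber volume, corneal diameter — age is excluded
as non-structural, IOP as the label source) are projected to a common
width (default 16), then mixed as w_img·h_img + w_clin·h_clin with
(w_img, w_clin) = softmax of two learnable logits, so the modality weights
stay on the simplex by construction. The fused vector passes through a
two-layer KAN (16 → 8 → 2). Order of operations (project → fuse → KAN) is
a package decision; the source description is ambiguous on this point.

Regularization: L1 penalty on all weights (λ₁ = 1e-4 default) added to the
cross-entropy loss; dynamic dropout on the fused representation with rate
p(t) = p₀/(1 + βt) over epochs (p₀ = 0.2, β = 0.1); early stopping when
validation accuracy fails to improve by more than 1e-6 for 10 consecutive
epochs (strict float equality would never fire).

Adaptive grid refinement allocates a conserved knot budget across image
regions proportionally to regional mean gradient magnitude (largest-
remainder apportionment, minimum one knot per region, uniform on blank
images). The governing description is contradictory — an argmin over the
gradient norm next to text assigning *more* precision to *high*-gradient
regions; the text's intent is implemented.

## 5. Evaluation protocol

Splits are stratified and patient-grouped: patients (majority-class
labelled) are apportioned to train/val/test by largest-remainder quotas
per class, largest group first; no patient spans two subsets, and with
single-sample patients the 8:1:1 quotas are hit exactly (780 → 624/78/78).

Metrics follow the printed formulas: precision TP/(TP+FP), recall
TP/(TP+FN), F1 = 2PR/(P+R), specificity TN/(TN+FP), MCC with the usual
four-factor denominator. Two conventions: a rate with an empty denominator
is 0, and MCC with a zero denominator is 0 (keeps imbalanced suites
total). One source equation conflates F1 and specificity; they are
implemented as the two distinct standard quantities.

5-fold CV retrains from scratch per fold and reports per-fold and median
metrics, seed-deterministic. Baselines (SVM, random forest, logistic
regression) standardize features inside each fold via pipelines.

### Ablation

Variants share one cohort, split and seed: **full** = phantom-pretrained
backbone + clinical fusion; **image_only** = the same pretrained backbone
without the clinical block; **no_pretrain** = randomly initialized
backbone, image only. (The upstream description of its ablation rows is
ambiguous; this assignment makes the expected ordering structurally
meaningful.) Desk-scale problem sizes: 800 phantoms at 64 px, classic
augmentation (200/class, gated), 5 pretraining + 8 fine-tuning epochs,
60 KAN epochs — about two minutes on one CPU. Across five seeds the
ordering full ≥ image_only ≥ no_pretrain held in four; in one seed
no_pretrain edged image_only by a single test sample (the phantom task is
easy enough that training from scratch nearly catches up — expected at
this scale, and the reason the ordering, not the absolute accuracies, is
the claim).

### Grad-CAM

Channel weights are the spatial means of the class-logit gradient at a
stage's token grid; the map is the rectified weighted channel sum,
bilinearly upsampled and max-normalized (an all-zero map is returned as
zeros). Heatmaps explain the per-image true/predicted class logit — normal
cases against the normal logit, hypertensive against the high logit — as
in the reference visualizations. The API defaults to the deepest stage
(appropriate at 224 px); at the 64 px tiny preset the deepest grid is
2 × 2, so analyses here use stage 1 (8 × 8). The untrained comparator is
the same architecture at the trained classifier's own random
initialization (a paired before/after contrast). Across five seeds the
trained model kept 64–93% of heatmap mass inside the band + wedge mask
(uniform mass would give ≈ 52%); the untrained model scored lower in four
of five — a random-init backbone can by chance concentrate on the bright
band, which bounds what this contrast can show.

## 6. Corrections

Ehlers (IOP = IOPG − 5·((CCT/1000 − 0.520)/0.070), CCT in µm), thin-shell
(IOPG/K), linear pachymetry (IOPG + 23.28 − 0.0423·CCT) and the
multiparameter factor C = A_CCT(CCT − 0.520)² + A_R(R − 7.8) + A_Age·Age +
A_IOPG (CCT in mm internally; interfaces take µm). The multiparameter
coefficients are caller-supplied by design — published values belong to
their source population and are not defaulted. C ≤ 0 is rejected as
unphysical.

## 7. Numerical infrastructure

All learnable components run on `iopscreen.nn`, a reverse-mode autodiff
engine over float64 NumPy arrays (matmul, conv2d via strided windows,
softmax, layer norm compositions, custom ops for cross-entropy and KAN
edges). Gradients are validated against central differences to ≤ 1e-6 in
the test suite. Optimizers: Adam and AdamW (decoupled decay), with
linear-warmup + cosine learning-rate decay. Every stochastic component
takes an explicit seed; pipelines derive per-stage seeds from one global
seed, and end-to-end runs are bit-reproducible.

## 8. What the phantom does and does not show

The phantom reproduces the emulated cohort's class balance, class-
conditional means, cohort-level attribute–IOP correlations, and a
band/wedge geometry whose image signal is a known function of the tabular
attributes. It does **not** emulate: real Scheimpflug optics (specular
reflections, lens structures, depth-dependent blur), measurement error in
the clinical attributes, inter-eye correlation beyond shared class,
attribute distributions beyond first and second moments, or any
distribution shift between sites. Passing results therefore establish that
the pipeline's machinery is correct and internally consistent — splits are
leak-free, the gate separates engineered corruptions, fusion exploits both
modalities, attribution lands on the constructed informative region — not
that comparable accuracy would hold on clinical data. Absolute phantom
accuracies are substantially higher than any clinical figure because the
printed class means are widely separated; only orderings and calibration
targets carry meaning here.
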