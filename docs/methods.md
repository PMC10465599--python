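# Methods

`leafdx` implements a classification pipeline for nutrient-deficiency
diagnosis from RGB leaf images of ridge gourd (*Luffa acutangula*), with
six classes: nitrogen-, phosphorus-, potassium-, calcium- and
iron-deficient, plus healthy. The stages are Gabor-filter pre-processing,
K-means region-of-interest (ROI) segmentation, a compact SqueezeNet-style
feature extractor trained with a from-scratch Adam optimizer, a hybrid
CNN–LSTM classifier with coarse and fine heads, and ring-toss-game
optimization (RTGO) for hyperparameter tuning. Because no field imagery
ships with the package, a seeded synthetic generator provides study-style
inputs; everything below states what each component assumes and where the
design was genuinely open.

## Synthetic leaf images

Each image is an elliptical leaf blade on a dark background (so
segmentation faces a real foreground/background task), with a stylized
phenotype per class: uniform yellowing (N; the green channel is lowered
relative to healthy tissue), purplish patches (P), a scorched margin ring
(K), apical necrotic spots (Ca), interveinal chlorosis with green veins
(Fe), and uniform green (healthy). The base pattern is a deterministic
function of (class, image size); the only stochasticity is additive
Gaussian pixel noise (std `noise_sigma` on the [0, 1] scale), clipped to
[0, 1]. Default class counts reproduce the reference survey's proportions
(2259/2250/1923/1910/2216/2142; 12,700 total); tests and the pinned
experiments use the same proportions scaled down, or balanced counts.
Defaults: 64×64 px (configurable up to 227×227), `noise_sigma` 0.05 as a
realistic camera-noise level; the pinned easy recipe uses 0.02.

What the generator does *not* emulate: lighting variation, pose/scale
jitter, occlusion, soil/stem clutter, intra-class symptom severity
gradation, or correlated (non-white) noise. Passing the end-to-end tests
therefore shows the pipeline machinery is correct and can learn
colour/texture phenotypes; it does not certify accuracy on photographs.

Stratified splits round half-up per class; residual drift against the
overall target count is corrected one image at a time starting from the
largest class, which keeps every class within 1/n_c of the requested
fraction and makes totals deterministic. The 80:20 and 70:30 presets
mirror the two reference protocols.

## Gabor pre-processing

The kernel is an isotropic Gaussian envelope (space constant ω, in
pixels) modulating a complex plane wave with frequencies (u, v) in
cycles/pixel:

    g(x, y) = 1/(2πω²) · exp(−(x²+y²)/(2ω²)) · exp(j2π(ux + vy)),

sampled at integer offsets on a (2·half_size+1)² grid. The phase is the
standard plane-wave form u·x + v·y. Filtering is true spatial convolution
(via `scipy.signal.convolve2d`), zero padding, same-size output, applied
to Rec. 601 luminance. The complex response becomes a real image by
taking the modulus and dividing by its maximum (standard Gabor-energy
practice); `real`/`imag` components are offered behind a flag. Defaults
ω=2, u=0.125, v=0, half_size=12 put the passband at an 8-px period, the
scale of vein/margin structure at 64×64.

## Segmentation and ROI

Pixels are clustered by Lloyd K-means under squared Euclidean distance in
RGB (optionally with the 3×3 local-mean luminance appended as a fourth
feature). Initialization picks k distinct points uniformly (seeded);
iteration stops when the inertia improvement falls below `tol` or at
`max_iter`; an emptied cluster is re-seeded at the point farthest from
its centroid; restarts keep the lowest-inertia solution. These rules are
pinned in-package so segmentations are reproducible bit-for-bit from the
seed (the library implementation in scikit-learn serves as an independent
cross-check in the tests, not as the implementation).

The ROI is the union of all clusters except the background cluster — the
one with the highest fraction of its pixels on the image border, ties
broken toward lower mean luminance. Background pixels are zeroed before
feature extraction. Default k=3 (healthy tissue / symptomatic tissue /
background). With k=3 on a two-tone image the background may split into
two clusters and one half then survives the border rule; this only leaves
extra (near-black) context in the ROI and did not affect classification
in any measured configuration. Optional plain histogram equalization is
available behind `equalize` as the pre-sharpening step.

## Feature extractor

A compact SqueezeNet-style network: stem 3×3 conv + ReLU + 2×2 average
pool, four fire modules (1×1 squeeze feeding parallel 1×1 and 3×3
expands, concatenated) with two more average pools interleaved, a deep
5×5 convolution (the one deliberately enlarged filter) + ReLU, dropout
(default 0.5), global average pooling, and a linear feature head. Every
convolution has stride 1; all downsampling is pooling, which keeps
activation maps large as long as possible. Counting graph nodes
(including the input node and each fire module's concat) the default
build has 39 layers; counting edges (a chain of 39 nodes plus one extra
parallel edge per fire module) it has 42 connections. That counting
convention is this package's own and is documented beside the builder.

No pretrained weights are used: the extractor is fitted on the train
split through a temporary 6-way softmax head (cross-entropy, Adam), after
which the head is dropped; a checkpoint hook allows loading externally
trained weights. Dropout sits before global pooling.

## Adam

Implemented exactly as the bias-corrected two-moment recursion with
defaults α=0.001, β₁=0.9, β₂=0.999 and the denominator offset η=1e−8
added *after* the square root. Stopping is a fixed step budget with an
optional gradient-norm tolerance. The optimizer operates on one flat
parameter vector; a shape registry packs and unpacks named arrays so the
same code trains both networks. All network layers implement analytic
backward passes (verified against central finite differences; observed
relative error ≤1e−6 away from ReLU kinks).

## CNN–LSTM classifier

Trunk: `[(CONV→RELU)×n_cr → POOL]×n_crp` with n_cr ≤ 5 (defaults n_cr=1,
n_crp=3 at desk scale, widths 8→16→32). The final feature map is read as
a sequence — each spatial row, flattened over channels and columns, is
one timestep — and consumed by a single-layer LSTM (input gate i,
bias-free tanh candidate g, forget gate f, output gate o; cell state
c_t = f⊙c_prev + i⊙g; h_t = o⊙tanh c_t). The last hidden state feeds a
coarse head over {deficient, healthy} and a fine head over the six
classes, in parallel by default; in the sequential arrangement the fine
head also sees the coarse probabilities (treated as a stop-gradient input
so the coarse head learns only from its own loss). The coarse label is
derived from the fine label (classes 1–5 → deficient, 6 → healthy).
Training minimizes CE(fine) + λ·CE(coarse), λ=0.5, with Adam.

Trunk input: by default the ROI-masked RGB image stacked with the
ROI-masked Gabor response as a fourth channel (`rgb+gabor`). A
Gabor-only input destroys the colour cues that distinguish the uniformly
coloured classes (yellowed vs green blades look alike after modulus +
per-image rescale), so colour is retained alongside texture; `rgb` and
`gabor` remain available for ablation. When the SqueezeNet extractor is
enabled (default) its feature vector is concatenated to the LSTM state
before the heads.

## RTGO

Population X (N×m) inside box bounds; the best max(1, round(0.10·N))
members are the score bars each iteration. Every member throws at one
uniformly assigned bar (uniform assignment because there are fewer bars
than members); per dimension, one draw r ~ U[0,1] supplies both the
factor F = round(1+r) ∈ {1,2} (half-up, so r ≥ 0.5 ⇒ F = 2) and the
displacement r·(sb−F·x) toward a better bar or r·(x−F·sb) otherwise.
Candidates are clipped to bounds (integral dimensions rounded) and
accepted only on strict improvement, so the best-so-far trace is
non-increasing by construction. One r per dimension (rather than per
member) was chosen for search diversity. Stopping is a fixed iteration
budget with an optional stagnation window. Minimization throughout.

For tuning, the 4-D space is (log₁₀ learning rate ∈ [−3.5, −2],
coarse-loss weight ∈ [0, 0.6], LSTM hidden units ∈ {8..48}, batch size ∈
{8..32}); the fitness is the validation error rate (100·wrong/total) of a
reduced-budget training run (default 3 epochs).

## Metrics

One-vs-rest per class: accuracy (TP+TN)/total — the only definition that
yields six distinct per-class accuracies — precision, recall,
specificity, F = 2PR/(P+R), and Matthews correlation, all ×100 so every
field shares the percent scale. Zero denominators yield 0 with a warning.
Macro averages are unweighted means; formatted output rounds half-up to
two decimals (with a 1e−9 pre-quantization so binary float error cannot
flip a .xx5 boundary) while full precision is kept internally. The report
also exposes `sensitivity` as an alias of macro recall, matching the
comparison-table naming.

## Reproducibility and problem sizes

All randomness flows from one root seed; stage seeds derive as
(root·100003 + offset·7919) mod 2³¹ and are logged in the run record.
Repeated runs of one config are byte-identical on manifests, masks,
feature CSVs and metric JSONs (the run record holds wall-clock timings
and is excluded). Images are 8-bit PNG; classifier inputs are rebuilt
from the 8-bit values so the in-memory and from-disk paths agree.

The pinned experiments are desk-scale by design: the end-to-end check
uses 300 images (50/class) at 64×64 with noise 0.02 and an 80:20 split,
20 training epochs, three seeds; tuning uses 120 images at 32×32 with
3-epoch fitness evaluations, a population of 4 and 3 iterations; the
sphere benchmark uses m=5, N=30, 200 iterations, 20 seeds. These sizes
were chosen once as the smallest configurations that exercise every
stage meaningfully.

## Known limitations

* Synthetic phenotypes are stylized; no claim transfers to photographs.
* The LSTM consumes rows of one feature map — sequence construction is a
  design choice, not a property of the data.
* The sequential head arrangement uses a stop-gradient on the
  coarse-probability input to the fine head.
* Gabor filtering is single-orientation/scale by scope; no filter bank.
* K-means uses random-point initialization (no k-means++); restarts are
  the mitigation.
* The histogram-equalization option is plain (not adaptive or fuzzy)
  equalization.
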