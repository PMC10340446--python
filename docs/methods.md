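# Methods

## Problem setting

`pneumoscope` screens chest radiographs for pneumonia without using any
labels at training time. The task is cast as one-class anomaly
detection: an autoencoder is fitted to radiographs of a single class
(either only pneumonia-positive or only pneumonia-negative images) and
asked to reproduce its input through a learned representation. A model
that has only ever seen one class reconstructs images of that class
with small error and images of the other class with larger error, so
the reconstruction error serves as an anomaly score and a threshold on
it yields a binary classifier.

Images are decoded to grayscale, resized to 64×64 with antialiased
bilinear resampling, and scaled to [0,1]. A radiograph is therefore a
point x ∈ [0,1]^u with u = 4096.

## Autoencoder variants

All four variants share a convolutional backbone: two or four hidden
3×3 convolution layers (16,16 filters, or 32,16,16,32), stride 1 with
same-padding, ReLU activations, and a single-filter 3×3 sigmoid output
layer producing the reconstruction y. Input and output have one
channel. Because there is no spatial downsampling, regularisation comes
entirely from each variant's objective, not from a bottleneck. The
two-layer model has 2,625 trainable parameters, the four-layer model
12,193 (convolutional stack only).

For an input x with reconstruction y, the per-sample reconstruction
cost is the summed squared error Σ_i (x_i − y_i)², or optionally the
Bernoulli cross-entropy −Σ_i [x_i log y_i + (1−x_i) log(1−y_i)] (with y
clamped to [ε, 1−ε], ε = 10⁻⁷). Squared error is the default since the
normalised pixels are real-valued. All logarithms are natural.

- **PCAE** (plain): reconstruction cost only.
- **DCAE** (denoising): during training each input pixel is
  independently set to zero with probability σ (zero-masking noise)
  while the clean image remains the reconstruction target. Corruption
  is applied only to training batches, never when computing validation
  or test errors.
- **SCAE** (sparse): a Bernoulli KL penalty
  γ Σ_j [z log(z/z̆_j) + (1−z) log((1−z)/(1−z̆_j))] pulls the mean
  activation z̆_j of each latent feature map toward the target z. The
  formulation is stated for scalar hidden units; for the convolutional
  backbone, z̆_j is the activation of hidden map j averaged over the
  batch and both spatial dimensions. ReLU activations are unbounded,
  so the average is squashed through the logistic function to land in
  (0,1) before entering the KL; z̆ is additionally clamped to
  [ε, 1−ε]. The penalty attaches to the middle of the stack (the
  encoder's final feature maps). γ is never pinned down by the source
  experiments; the default is 0.1 and it is exposed in configuration.
- **β-VCAE** (beta-variational): the encoder's feature maps are
  flattened through two dense layers into the mean μ and log-variance
  of a diagonal Gaussian posterior over a latent code of dimension d
  (default 32); the decoder re-enters the convolutional stack through a
  dense layer and reshape. Training samples the latent via the
  reparameterization z = μ + ε⊙σ and adds the closed-form KL to the
  isotropic unit-Gaussian prior, weighted by β:
  β · ½ Σ_d (μ_d² + e^{lv_d} − 1 − lv_d). β = 1 recovers the
  conventional VAE; β > 1 buys a smoother, more structured latent
  space at some reconstruction cost. At evaluation time the latent is
  fixed at μ, so eval-mode scoring is deterministic.

Setting σ = 0 or γ = 0 reduces the corresponding variant to the plain
autoencoder exactly — bit-equal losses and gradients at shared
parameters — which the test suite asserts.

Weights are initialised with fan-balanced (Glorot) uniform draws from a
seeded generator; biases start at zero. Building the same spec and seed
twice yields identical parameters.

## Training

Optimisation is classical momentum SGD (not Nesterov): initial learning
rate 0.1, momentum 0.9, batch size 32, 10 epochs, with the rate decayed
by a factor 0.2 every 3 epochs. With 0-based epoch index e, the rate is
0.1·0.2^⌊e/3⌋, giving the trace 0.1×3, 0.02×3, 0.004×3, 0.0008×1. There
is no early stopping.

The trainer minimises the objective divided by B·u (batch size times
pixel count), i.e. the per-pixel, per-sample mean rather than the raw
sum over pixels. The two are equivalent up to a constant rescaling of
the learning rate, but at a fixed rate of 0.1 the summed form produces
steps four thousand times too large and diverges immediately; the mean
form is the scale at which the stated rate is meaningful. The β and γ
weightings relative to the reconstruction term are unaffected (the
whole objective is scaled, not individual terms).

One training seed is fanned into named substreams (shuffling,
corruption, reparameterization) so that, e.g., changing σ cannot
perturb the shuffle order, and weight initialisation is driven by a
separate model seed entirely.

## Scoring, threshold and decision rule

The anomaly score of an image is its eval-mode mean squared pixel
error. Mean rather than summed error is used because the two are
threshold-equivalent at fixed image size and the mean is stable under a
change of resolution. For the β-VCAE the score is the reconstruction
term only, from the deterministic μ-latent — the thresholding rule
concerns reconstruction quality, not the full training objective.

The decision threshold is the **maximum** reconstruction error over the
validation set (which belongs to the trained-on class). An image is
called anomalous iff its error strictly exceeds the threshold; ties
break to the trained-on class. Two consequences are asserted as
invariants: every validation image is classified as the trained-on
class, and the number of anomaly calls is non-increasing in the
threshold.

## Splits

The trained-on class is shuffled with a seeded permutation and
partitioned 60/20/20 into train/validation/test; the entire opposite
class is additional test data. Counts use round-half-up on 0.6n and
0.2n with the remainder going to test: this is the unique simple
rounding rule that reproduces both reference partitions, 3875 →
2325/775/775 and 1341 → 805/268/268 (0.6·1341 = 804.6 → 805).

## Evaluation

The positive class is pneumonia regardless of which class was trained
on. From the confusion counts: recall R = TP/(TP+FN), precision
P = TP/(TP+FP), f1 = 2RP/(R+P), and f2 = 5RP/(R+4P). f2 weights recall
four times as heavily as precision because a missed pneumonia is the
costliest error; accordingly f2 > f1 exactly when R > P. Metrics whose
denominator is zero are reported as undefined flags, never as silent
zeros. Values are kept at full precision internally and rounded
half-up to two decimals only at report rendering.

## Synthetic data

The generator emulates the statistical structure the one-class framing
needs, not radiographic realism. A "normal" image is a smooth torso
gradient with two bright elliptical lung fields (slight per-image
jitter of position, size and amplitude), a dim mediastinal column,
Gaussian smoothing, and additive pixel noise (default sd 0.02), clipped
to [0,1]. An "anomalous" image is built from the identical background
and noise draws plus 1–3 bright circular opacity blobs (radius 4–9 px,
peak added contrast 0.4, quadratic falloff) composited inside the lung
ellipses — pneumonia consolidations appear bright on a radiograph, and
restricting blobs to the lung fields makes them context violations the
model should fail to reconstruct, rather than background artifacts.

Blob count, radius, contrast and noise are calibration knobs of the
benchmark, not claims about lesion morphology. Defaults were chosen
once so that the anomaly signal (mean-error bump of order contrast² ×
blob area / u) sits clearly above the noise floor yet well below
trivial separability. The seed is split into named substreams
(background, noise, blobs), so an anomalous image with zero blobs is
pixel-identical to the normal image of the same seed — the degenerate
case the test suite exploits.

What the generator does **not** emulate: anatomical variability between
patients, acquisition differences (exposure, positioning, equipment),
diffuse or bilateral consolidation patterns, rib and soft-tissue
texture. Passing the synthetic recovery benchmark therefore shows that
the pipeline end-to-end learns a one-class model and detects localized
reconstruction-context violations at realistic contrast; it does not
certify performance on clinical radiographs.

## Benchmark protocol and problem sizes

The synthetic recovery benchmark trains on 300 normal images, fits the
threshold on 100 validation normals, and evaluates on a balanced
200-image test set (100 held-out normals, 100 anomalous), using the
full reference schedule. The package's acceptance checks run this
protocol for the four-layer β-VCAE (β = 5) and the plain autoencoder at
two replicate seeds (tests) or one (acceptance script), asserting
f2 ≥ 90% for the variational model and that its mean f2 does not fall
below the plain autoencoder's. Unit tests use smaller image sets
(30–60 images) and the two-layer backbone.

## Numerical choices

- float32 arithmetic in the network stack (float64 for loss
  accumulation and scoring); the gradient-check tests switch the stack
  to float64 to compare against central finite differences.
- ε = 10⁻⁷ clamps for every logarithm argument (sigmoid saturation and
  dead ReLU maps otherwise produce infinities).
- Convolution is implemented as one GEMM of the padded input against
  all nine kernel taps with shifted-view accumulation, which avoids
  materialising im2col column matrices; backward uses the mirrored
  scatter plus two GEMMs.
- Non-finite training loss aborts with an error naming the epoch and
  batch rather than continuing silently.
- PNG fixtures are 8-bit; loading is exact to 1/255.

## Known limitations

- The variational head's dense layers dominate the parameter count
  (≈6.4 M at d = 32 on 64×64 maps); the reference architecture's exact
  latent layout is not recoverable from its description, so the head is
  a documented design choice with d configurable.
- No GPU path; training cost is a few minutes per model on one CPU
  core at the benchmark sizes.
- Binary screening only; the one-class construction does not extend
  directly to multi-class diagnosis.
- Percentile or ROC-optimised thresholds are deliberately not provided
  as defaults; the max-validation-error rule is the reference
  behaviour.
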