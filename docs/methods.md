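# Methods

## Problem and pipeline

EEG-based emotion recognition suffers from small training sets: one
subject's session yields a few thousand one-second segments at best.
`eegaug` implements a generative data-augmentation pipeline for this
setting. EEG segments are converted to differential-entropy (DE)
topographic images; one generative model per emotion class learns the
distribution of those images; samples drawn from the trained generators
are mixed into the classifier's training set.

Stages, each a library module:

1. **features** — DE per channel and band, temporal smoothing, scalp-map
   rendering.
2. **generative** — the VAE-D2GAN networks and losses.
3. **training** — the alternating optimization loop, one model per
   emotion, augmented-set assembly.
4. **classifier** — a convolutional network with adaptive batch
   normalization (AdaBN) used to measure augmentation benefit.
5. **evaluation** — Inception Score, FID and MMD for generated-sample
   quality.
6. **synthetic_data** — band-structured surrogate EEG and toy mixtures
   that give every stage a recoverable ground truth without any dataset
   download.
7. **cli / pipeline** — a thin command-line and one-shot `run_pipeline`
   wrapper.

## Feature model

For a zero-mean Gaussian signal with variance σ², the differential
entropy is h = ½ ln(2πeσ²) (nats). Per channel and per band
(δ 1–4, θ 4–8, α 8–14, β 14–31, γ 31–50 Hz) the band variance is
estimated as the integral of the Welch power spectral density over the
band's bins — mean short-time Fourier power with Hann windows at 50%
overlap, corrected for window power. The window length is
min(2 s, segment length): a 1 s window leaves the 3-Hz-wide delta band
with so few bins that log-estimator bias and edge leakage reach ~6%,
while 2 s brings the worst band under 3.5%; segments shorter than 2 s
degrade gracefully to a single full-segment window. Zero-variance
channels are clamped to a configurable variance floor (default 1e-12)
so silent inputs give finite features.

DE trajectories are smoothed per channel × band by a linear dynamic
system: a random-walk state-space model (process variance q = 1e-3,
observation variance r = 1e-1, both configurable) whose posterior mean
is computed by a Kalman filter with diffuse initialization plus an RTS
backward pass. q ≪ r expresses that the underlying affective state moves
slowly relative to segment-to-segment estimation noise.

Smoothed features are rendered as a 5 × 32 × 32 image stack: per band,
channel values are scattered at planar electrode positions and
interpolated with a piecewise-cubic Clough–Tocher scheme (exact for
planar fields, exact at electrode nodes); pixels outside the electrode
convex hull take the nearest electrode's value. Electrode positions come
either from an azimuthal-equidistant projection of standard 10–20
template positions (via mne, optional) or from a quasi-uniform synthetic
sunflower montage. Image rows run anterior (row 0, nose) to posterior.
Each band is min–max scaled to [0, 1] with a *session-level* normalizer
so all maps of one training set share one scale; a degenerate band
(min = max) maps to zero. The [0, 1] codomain matches the generator's
final ReLU, so real and generated samples live in the same space.

## Generative model

VAE-D2GAN couples a variational auto-encoder with a dual-discriminator
GAN. Encoder E maps an image to a Gaussian posterior N(μ, diag e^{2λ})
(two parallel dense heads for μ and λ = log σ); the latent draw is
reparameterized z = μ + γ ⊙ e^λ, γ ~ N(0, I). Generator G decodes z; it
is shared between the VAE (reconstruction) and the GAN (fooling the
discriminators on both encoded z and prior draws z_p ~ N(0, I)).
D1 scores realness and is rewarded by log D1 on real data; D2 scores
"generatedness" and is rewarded by log D2 on generated data. The
objectives (batch means):

    L_KL  = E KL(N(μ, diag e^{2λ}) || N(0, I))
    L_Rec = E ||x − G(z)||²
    L_G   = −(E D1(G(z)) + E D1(G(z_p))) + β (E log D2(G(z)) + E log D2(G(z_p)))
    L_D1  = α E log D1(x) − E D1(G(z)) − E D1(G(z_p))          (maximized)
    L_D2  = β E log D2(G(z_p)) + β E log D2(G(z)) − E D2(x)    (maximized)

with α, β ∈ (0, 1] damping the log terms (defaults α = 0.2, β = 0.1).
With discriminators reduced to one free positive scalar s, L_D1 is
maximized at s = α/2 and L_D2 at s = 2β — the closed forms used as
test oracles.

Architecture (image models): encoder/discriminators are three 5×5
stride-2 convolutions (base → 2·base → 4·base channels, ReLU) and a
dense layer; the generator mirrors them with transposed convolutions and
a final ReLU. The published configuration is base = 64 with latent
dimension 128; both are constructor parameters, and the desk-scale test
configuration uses base 8–16 with latent 16–32 so the training-based
checks fit a single-CPU budget. A dense variant (two hidden layers,
linear output) adapts the same model to low-dimensional diagnostics
where samples are signed. No normalization layers appear in E, G, D1 or
D2.

Numerical choices:

* **Initialization.** He-scaled truncated normal (std √(2/fan_in),
  truncated at 2σ). These networks carry no batch normalization, so a
  fixed small init (the DCGAN-style 0.02) collapses forward signal
  propagation and stalls or destabilizes training; He scaling is the
  standard propagation-preserving choice for ReLU stacks.
* **Score positivity.** Discriminators end in softplus, which is
  positive mathematically but underflows to 0 in float32; scores are
  floored at 1e-6 inside every log and reciprocal.
* **Precision.** All network arithmetic is float32 (loss accumulation in
  float64); convolutions are im2col GEMMs with numba-jitted patch
  gather/scatter and a pure-NumPy fallback.

## Training

One iteration on a real mini-batch (batch 16, Adam, learning rate 1e-4
by default): one ascent step on L_D1 in D1, one on L_D2 in D2, then one
joint step in which E descends L_KL + L_Rec and G descends L_Rec + L_G
(the generator backward pass runs twice — reconstruction-only and
adversarial — so the encoder receives exactly the L_KL + L_Rec gradient
while G accumulates both parts). The loop is a pure function of
(data, seed): histories and parameters are bitwise reproducible.

For the desk-scale experiments in the test suite, the learning rate is
raised (the publication-scale 1e-4 is matched to far longer schedules
than a 2,000-iteration budget) — see the acceptance tests for the exact
configurations used.

One model is trained per emotion class, seeded seed + class, so models
are independent but reproducible. Generation draws z_p ~ N(0, I) through
each class's generator and clips images to [0, 1]. Augmented training
sets add a class-balanced subset of generated samples (largest-remainder
apportionment; a short class pool triggers a warning and the nearest
balanced split).

## Classifier and AdaBN

The downstream classifier mirrors the discriminator stack (widths
configurable) with a 128-unit dense layer and softmax head; an adaptive
normalization layer follows every convolution and dense layer. During
training, normalization uses batch statistics; after training, per-layer
statistics are stored per domain tag (real / generated kept as separate
domains by default; pooling is a config switch). At prediction time the
statistics are recomputed in one pass over the target domain's data,
which absorbs global distribution shifts — a per-feature affine shift of
the inputs is removed by the first normalization layer up to convolution
border effects, giving ≥99% prediction agreement on shifted copies.

## Quality scores

* **IS** — exp of the mean KL between conditional and marginal class
  posteriors of the package's own trained classifier (substituting for
  Inception v3); bounded by [1, K].
* **FID** — Fréchet (Wasserstein-2) distance between Gaussian fits to
  penultimate-layer embeddings; covariances are regularized by 1e-6·I
  before the matrix square root (the regularizer is a parameter and the
  closed-form tests set it to 0).
* **MMD** — biased squared-MMD with an RBF kernel on flattened raw maps;
  bandwidth by the median heuristic over pooled pairwise distances
  (fallback 1 when degenerate). The kernel and bandwidth are recorded in
  every QualityReport.

## Synthetic data

Each synthetic EEG channel is a sum of five band-limited Gaussian noise
processes (FFT-domain masking — exact band confinement makes the
variance recoverable) scaled so the *expected* band variance equals an
emotion profile's target, plus a white noise floor. Default profiles
share a 1/f-flavoured baseline (δ strongest) and give each class a
smooth channel-block bump in β and γ power — a crude surrogate for
high-band emotional asymmetries, calibrated only to make classes
separable from true DE features. The generator reproduces band structure
and spatial smoothness but none of EEG's nonstationarity, artifacts,
cross-channel phase structure, or genuine affective physiology: passing
tests demonstrate the pipeline's correctness and the augmentation
mechanism, not performance on real recordings.

The mode-collapse diagnostic is the classic ring of K = 8 Gaussians
(radius 2, σ = 0.05): a generative model is trained on ring samples with
the dense variant and scored by how many components hold ≥1% of
generated samples within 3σ of their mean. The default budget for this
diagnostic is 8,000 iterations at batch 64 with learning rate 1e-3 and
hidden widths (64, 64); batch 16 is far less stable here (the per-batch
mode sample is too sparse to hold all eight modes in play), which is why
the toy diagnostic departs from the image models' batch size.

## Problem sizes used by the tests

Training-based checks run the full algorithm at reduced width (base 4,
latent 8, learning rate 1e-3): 2,000 iterations on 64 single-class maps
(distribution recovery), a 3-class task with 60 real maps per class and
1,000 generated per class (augmentation benefit), and the 8-Gaussian
ring (mode coverage), each over 5 seeds. These sizes were chosen once so
the whole suite runs on one CPU in minutes; the published-scale
configuration (base 64, latent 128, 8,000 samples per emotion) is
exercised for shape/loss correctness but not trained to convergence in
tests.

When two MMD values are *compared* (generated vs a noise reference
against the same real set), both are computed with one common bandwidth
— the median heuristic on the real set alone — because the per-call
median heuristic would place the two comparisons in different RKHSs and
make the ordering meaningless. Stand-alone MMD reports keep the default
per-call heuristic and record the bandwidth used.

## Known limitations

* No artifact/EOG handling beyond what the feature model implies; no
  PSD/DASM/RASM features; no sample-selection strategy for filtering
  low-quality generated samples.
* The exact electrode-to-pixel mapping of the original topographic-map
  construction is not recoverable from public sources; the
  azimuthal-equidistant projection here is a documented stand-in, and
  montages with non-standard electrodes need explicit positions.
* Whether MMD should be computed on raw maps or classifier embeddings is
  ambiguous in the literature this follows; raw flattened maps are the
  default and embeddings are available through the same API.
* The desk-scale generative runs demonstrate distribution learning, not
  the publication-scale image quality a GPU run of the base-64
  configuration would reach.
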