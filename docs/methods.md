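# Methods

## Model

`cgad` implements classification by label-space diffusion. The object that
diffuses is not the image but a K-dimensional class-score vector: during
training the clean state `y0` is the one-hot encoding of the ground-truth
label; at inference the classifier's predicted distribution stands in for
it. A forward Markov chain of `T` steps corrupts the state with Gaussian
noise; a conditional network learns to predict the injected noise; the
reverse chain recovers a clean score vector whose argmax is the prediction.

The departure from a textbook DDPM is **confidence-guided adaptive noise
injection**: the noise term is scaled per sample by `(1 - c)`, where
`c = max_k softmax(classifier(x))_k` is the maximum posterior probability
of an auxiliary classification head, and a guidance vector `G` derived from
image priors shifts the state:

    y_t = sqrt(abar_t) * y0 + sqrt(1 - abar_t) * (1 - c) * eps + (1 - abar_t) * G

Low-confidence (semantically ambiguous) samples are perturbed strongly,
encouraging exploration; high-confidence samples keep their semantics
nearly intact. `c` is always detached: it modulates magnitudes but carries
no gradient, so the mechanism stabilizes optimization without altering the
discriminative objective. The clean-state estimator inverts the forward map
exactly (given the true noise), and the reverse transition applies the
standard two-coefficient DDPM posterior to the guidance-shifted variable
`z_t = y_t - (1 - abar_t) * G`, shifting back by `(1 - abar_{t-1}) * G` —
the unique construction that keeps a noiseless chain consistent with the
forward marginals. Reverse-chain sampling noise is likewise scaled by
`(1 - c)`, so a fully confident sample follows a deterministic path.

The priors come from a structure-aware network: a stride-8 residual
encoder feeds two complementary context blocks — a hierarchical pyramid
context module (parallel standard + dilated 3x3 convolutions at rates
{2,4,8}, concatenated and projected) and an intra-scale dilated-convolution
refinement block (sequential rates (1,2,4) in a residual connection;
receptive field 1 + 2*(1+2+4) = 15 for 3x3 kernels). Their concatenation
yields a global prior score vector `y_g`, a single-channel spatial response
map whose best window (exhaustive-equivalent integral-image search,
bilinear upsampling to pixel coordinates, ties to the smallest row/col)
selects a region of interest, and a pooled latent `rho(x)`. The cropped
region passes through a small residual pathway with squeeze-and-excitation
channel attention (bottleneck ratio 4) to the local prior `y_l`; a
projection of the concatenated penultimate features gives the fused prior
`y_f` and the auxiliary classifier logits.

## Training objective

    L = L_denoise + lambda * (L_MMD + L_aux) + L_recon,     lambda = 0.5

* `L_denoise`: squared error between injected and predicted noise (sum over
  entries, mean over batch).
* `L_MMD`: multi-view maximum mean discrepancy. Two extra denoising paths
  share the network but condition on `y_g` and `y_l` alone; the biased
  V-statistic MMD (Gaussian kernel, five bandwidths geometrically spaced
  around the median pairwise distance of the pooled batch) aligns each
  branch's noise-prediction distribution with the true noise. The fused
  branch does not enter `L_MMD`.
* `L_aux`: cross-entropy of the auxiliary head, active at fixed *step*
  intervals (`aux_period`, default every 5 optimization steps). Step-level
  periodicity keeps the confidence head calibrated to the evolving
  features; with epoch-level activation we observed the head going stale
  between activations, producing spuriously saturated confidence.
* `L_recon`: per-branch mean squared error between each denoised prior and
  its clean counterpart (targets detached). The clean-state estimate
  amplifies residual noise by `1/sqrt(abar_t)`, which at deep steps is a
  factor of ~25 at the default schedule; the reconstruction is therefore
  compared in `sqrt(abar_t)`-scaled space (signal-to-noise weighting,
  standard for clean-state-parameterized diffusion losses). Without this
  weighting the term dominates the objective by three orders of magnitude.

The decomposition identity `L = L_denoise + lambda*(L_MMD + L_aux) +
L_recon` holds exactly (bitwise) on every logged step.

## Guidance

The forward equation adds a prior-derived guidance term while the
denoising equation subtracts a prior-center term; for algebraic
invertibility one configurable vector `G` is used in both
(`guidance_mode`): the prior sum (default) or an exponential moving
average (decay 0.99) of the terminal states as a running prior center.
Within the prior-sum mode, `guidance_source` selects between the clean
prior sum `y_g + y_l` (default) and the branch-denoised estimates at the
sampled step. The clean source is the default because (i) its scale is
stable — the denoised estimates inherit the `1/sqrt(abar_t)` noise
amplification at deep steps, which destabilized training in our
experiments — and (ii) it makes the train-time and test-time conditioning
distributions identical. The denoised priors still participate in the
objective through the reconstruction and MMD terms.

## Inference

Evaluation runs the full reverse chain per image. Confidence comes from
the auxiliary head's softmax on the image alone; guidance is the clean
prior sum. Because no ground truth exists at test time, the terminal state
is seeded by forward-diffusing the classifier's predicted distribution
(the model prediction standing in for `y0`). This keeps the chain
informative at every confidence level: at `c -> 1` the chain reduces to a
noiseless round trip through the predicted distribution; at low `c` the
denoiser and the stochastic exploration dominate. The prediction is the
argmax of the recovered clean vector, optionally averaged over
`n_samples` independent chains (library default 1). A single chain is a
one-sample Monte-Carlo estimate of the model's expected clean vector and
carries visible readout noise on small test sets; the desk-scale metric
reports in the tests and the reproduction script therefore average 3
chains per image.

## Numerical and design choices

* **Schedule.** Linear `beta` from 1e-4 to 0.02 over `T = 1000` is the
  library's full-scale default. Desk-scale configurations use `T = 200`
  with `beta_end = 0.1`, chosen so the terminal signal level
  `abar_T ~ 3e-5` matches what the full-scale schedule produces; keeping
  `beta_end = 0.02` at `T = 200` would leave `abar_T ~ 0.13`, i.e. a
  terminal state still 13% signal-bearing, and a mismatch between the
  training marginal and the sampling initialization.
* **Float64 everywhere.** The networks are small; the diffusion algebra
  tests require 1e-9 round-trip accuracy.
* **Heads.** Score heads (`y_g`, `y_l`, `y_f`) use small-normal init
  (sd 0.01) so the guidance starts near zero; the auxiliary head and the
  denoiser output start at exactly zero, making the initial confidence
  exactly `1/K` and the initial noise prediction neutral.
* **Feature normalization.** Pooled features are scaled to unit
  root-mean-square before every head. Without this, feature magnitudes
  drift under the mixed objective and the classifier logits (and hence the
  confidence) saturate for reasons unrelated to classification quality.
* **Optimization.** Adam at 1e-3 with cosine annealing to zero; global
  gradient-norm clipping at 25 (diffusion-loss gradients occasionally
  spike an order of magnitude above their typical norm of ~20-50).
* **Determinism.** One master seed; separate generator streams for
  initialization, data order/augmentation, noise draws, and evaluation.
  Everything is single-threaded numpy; equal seeds give bitwise-equal loss
  trajectories.
* **Ties.** `argmax` ties (confidence, ROI search, prediction) break to
  the first/smallest index.
* **Degenerate inputs.** Single-class datasets, non-normalized probability
  vectors, out-of-range steps, mismatched vector lengths and non-finite
  loss parts raise immediately with the offending quantity named.

## Synthetic benchmark

The generator renders per class an elliptical lesion-like blob — radial
Fourier boundary perturbation, Gaussian-filtered fill texture, boundary
blur — on a skin-tone background. Class identity is carried by a
six-parameter vector (eccentricity, irregularity amplitude, lobe count,
darkness, texture contrast, size). The `ambiguity` knob interpolates every
class's parameters toward the global mean and widens boundary blur:
ambiguity 0 gives near-zero Bayes error; ambiguity 1 makes class
distributions identical, so no classifier can beat chance in expectation.
Heterogeneous per-sample difficulty (hence heterogeneous confidence) is
exactly the regime adaptive injection targets. Splits are stratified 80/20
and stored in the manifest; same spec and seed reproduce byte-identical
PNGs.

What the generator does **not** emulate: dermoscopic artifacts (hair,
rulers, ink), class imbalance, label noise, resolution heterogeneity, or
realistic texture statistics. Passing tests on this benchmark demonstrate
that the machinery is implemented correctly and learnable end to end, not
that the method attains any particular accuracy on clinical data.

## Problem sizes

Tests and the reproduction script run at desk scale, as the package's own
choice of study conditions: 64x64 images, 48 images per class for the
separability benchmark (two classes, ambiguity 0, 50 epochs, T = 200,
8-channel backbone, width-64 denoiser), and 48x48 images, 24 per class,
ambiguity 0.8, 10 epochs, T = 60 for the stability harness (two cells x
three seeds). The full-scale protocol (224-scale inputs, batch 64, 1000
epochs, T = 1000) remains available via `TrainingConfig.paper_protocol()`.

## Known limitations

* The confidence is an uncalibrated proxy (maximum softmax); the method's
  premise degrades if it saturates early, which the step-periodic
  auxiliary supervision and feature normalization mitigate but do not
  eliminate.
* One region of interest per image; multi-ROI aggregation is out of scope.
* The autodiff engine implements exactly the operations these networks
  need; it is not a general-purpose framework (no broadcasting matmul over
  batched 3-D operands, no strided convolution — downsampling is by
  pooling).
* Reverse sampling is the plain ancestral chain; accelerated samplers are
  out of scope.
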