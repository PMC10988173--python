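# Methods

This note records the modeling choices, parameterizations and numerical
conventions behind `blindpick`, in the spirit of a model-description page:
what is assumed, what is tunable, and what the synthetic studies do and do
not demonstrate.

## Observation model and denoiser

Each micrograph pixel is modeled as `y = x + n`, with a univariate Gaussian
prior on the clean signal, `x ~ N(mu_x, sigma_x^2)`, whose parameters a
blind-spot network predicts from the pixel's context, and zero-mean Gaussian
noise of std `sigma_n`. Two noise families are supported:

* `gaussian` — `sigma_n` free, learned by the auxiliary estimator;
* `poisson_approx` — `sigma_n^2 = a * max(mu_x, eps)`, a signal-dependent
  Gaussian approximation to Poisson counting noise with gain `a`. The prior
  mean `mu_x` (the model's best clean estimate) is used as the signal
  surrogate so the loss stays differentiable; `eps = 1e-4` floors the
  variance for non-positive signal.

Both the marginal likelihood of `y` and the posterior mean of `x` are then
closed-form; the additive constant of the negative log marginal is dropped
from all reported losses. Positivity of `sigma_x`, `sigma_n` and `a` is
enforced by softplus plus a floor of `1e-4`.

**Homoscedastic noise scale.** The noise estimator is an ordinary (non
blind-spot) U-Net, so it sees each pixel's own value. If its per-pixel
output were used directly, likelihood training would collapse onto
`sigma_n(i,j) ~ |y(i,j) - mu_x(i,j)|` pointwise — a degenerate optimum
(mean NLL `0.5 + 0.5 E[log r^2] < 0.5`) that destroys the noise-level
estimate while looking like a lower loss. The estimator output is therefore
pooled to a single value per image and broadcast: the noise level (or
Poisson gain) is treated as constant within a micrograph, which matches how
exposure and detector statistics actually vary. Under the Poisson model the
per-pixel noise std still varies spatially through `mu_x`.

**Prior-variance shrinkage.** On featureless data the marginal constrains
only the sum `sigma_x^2 + sigma_n^2`, so the split between prior and noise
variance is unidentifiable and drifts. A small penalty
`sigma_x_shrinkage * mean(sigma_x^2)` (default `1e-3`) resolves the tie in
favor of the noise: variance is attributed to `sigma_x` only where residuals
demand it locally. With it, training on flat sigma = 2 noise recovers the
noise std to within a percent; without it the split is arbitrary.

## Blind-spot backbone

The feature extractor is a U-Net with three encoder and three decoder
levels, skip connections, LeakyReLU(0.1), max-pool downsampling and
nearest-neighbor upsampling (avoids checkerboard artifacts). Channel widths
are `c, 2c, 4c` with `c = base_channels` (32 by default, 16 in the
desk-scale studies). In blind-spot mode every 3x3 convolution is vertically
causal (padded (2,0)), each branch shifts its features down one row before
every pool (otherwise the down/up round trip leaks one row), and after the
decoder the features shift down one final row. Run on the four quarter-turn
rotations of the input and recombined by 1x1 heads, the receptive field of
every output pixel is the union of four half-planes — everything except the
pixel itself. This is an architectural guarantee, independent of the
weights; the tests assert exact equality under single-pixel perturbations
and an exactly zero input gradient, via the package's own reverse-mode
autodiff.

Heads are two-layer 1x1 convolution stacks. The final layer of each head is
initialized near zero so the initial outputs equal the head biases:
`mu_x = 0` (the standardized mean), `sigma_x = softplus(-4) ~ 0.018`
(confident prior), `sigma_n = softplus(0.54) ~ 1` (all variance initially
attributed to noise — the sensible starting point in a regime where noise
dominates), and the detection logit at `logit(pi)` — the standard
prior-probability initialization of one-stage detector heads. Without the
last one, a desk-scale schedule cannot move the background logit from 0 to
`logit(pi)` and detection stalls.

Inputs are standardized per image (subtract mean, divide by std) for the
Gaussian model; for the signal-dependent model the image is only divided by
its std, since the variance law `var = a * signal` survives scaling but not
shifts. Outputs are un-standardized on write; checkpoints record the
convention.

## Positive-unlabeled detection

Ground-truth heatmaps splat each annotated center as a Gaussian bump of std
`sigma_p = max(1, radius/3)` (3-sigma support at the particle boundary),
value exactly 1 at the center, overlaps resolved by max. The detection loss
is

    pi * E_labeled[-(1 - p)^alpha log p]  +  GE(p_unlabeled; pi)

with `alpha = 2` (and `beta = 4` in the standalone penalty-reduced focal
loss, which keeps both branches). The GE term draws K unlabeled pixels
(training default K = 256) outside any labeled splat and compares the
induced count distribution — a Poisson-binomial, computed by the exact
O(K^2) dynamic program — to Binomial(K, pi).

**Divergence direction.** The KL runs empirical-first:
`KL(PoissonBinomial || Binomial)`. The opposite direction is qualitatively
wrong here: a *correct, confident* detector induces a nearly deterministic
count, and a prior-first KL then diverges (scale `K pi (1-pi)`), so training
equilibrates at `p = pi` everywhere and detection never sharpens — we
measured F1 0.07 vs 0.95 for the two directions under identical conditions.
Empirical-first, confidence costs only a small entropy-like term. The
gradient of the exact KL is analytic: leave-one-out pmfs are obtained by
deconvolving each Bernoulli factor (forward recurrence for p <= 1/2,
backward otherwise), O(K^2) total, verified against central differences. A
moment-matching surrogate (`gaussian_approx`: squared mean gap plus squared
variance gap, normalized by the binomial variance) is provided and
cross-checked, but the exact DP is cheap enough to be the training default.

The class prior follows the visual-inspection heuristic
`pi = n_particles * pixels_per_particle / total_pixels` (clipped to
(1e-6, 0.49)), with `pixels_per_particle = pi_circle * radius^2`.

## Training

Total objective `lambda_den * denoise + lambda_det * detect +
lambda_cons * consistency` with defaults 1.0 / 0.1 / 0.1 — denoising is the
dominant task; detection refines shared features rather than creating them.
Single-task modes zero the other head's loss and exclude its parameters
from the optimizer (denoise-only provably never touches the detection
head).

Patches (square, default 48 px at desk scale; divisible by `2^depth`) are
sampled so each contains at least one labeled particle; a denoise-only run
on unannotated data falls back to uniform patches. Patches are augmented by
a random dihedral transform (labels moved along) — without this the
over-parameterized blind-spot net memorizes the fixed noise realizations of
a small dataset (train residual 0.72 vs fresh 1.07 in the flat study).
Consistency draws one additional transform per sample and penalizes the MSE
between transformed outputs and outputs of transformed inputs, for both the
heatmap probabilities and the posterior-mean denoised image (both terms are
exposed as switches; the heatmap term is the one the equivariance claim is
about, the denoised term empirically helps).

Augmentation and consistency interact: with dihedral input augmentation on,
even a `lambda_cons = 0` model becomes nearly equivariant at desk scale
(heatmap gaps ~2e-4), so the consistency ablation is run with input
augmentation disabled in both arms — same data and seed, only `lambda_cons`
differing — where the regularizer's effect is cleanly measurable (gap ratio
~1.5x in its favor).

Adam, batch 16 at full scale and 4 in the desk studies, linear warm-up from
zero over the first 10% of iterations then cosine decay to zero, early
stopping when the windowed mean loss changes by < 1% (window 200), global
gradient-norm clipping at 10 (the likelihood loss has a log-flat
large-variance basin that early large gradients can otherwise jump into).
`lr_peak = 2e-3`: at a few hundred iterations, 5e-4 measurably undertrains
(held-out prior-mean MSE 0.12 vs 0.026) and 5e-3 destabilizes the joint
objective. Runs are bit-reproducible for a fixed config seed.

## Inference and evaluation

Whole micrographs are standardized, reflect-padded to divisibility by
`2^depth`, forwarded once, cropped and un-standardized. Picking applies
greedy NMS over supra-threshold heatmap pixels (descending score, ties by
row-major position) with radius equal to the particle's half major-axis
length, at a default probability threshold of 0.5. Matching for
precision/recall is greedy, score-ordered and one-to-one; 0/0 ratios are
reported as 0. PSNR takes its range from the reference image (float
micrographs have no fixed dynamic range). FSC is computed over integer
Fourier shells with the resolution read at the 0.143 crossing by linear
interpolation. Coordinates are 0-based with x = column, y = row everywhere,
including EMAN .box conversion (corner + box/2).

## Synthetic studies: scope and limits

The generator places Gaussian-blob particles (std = radius/2, so ~2-sigma
support at the stated radius) or hard disks on a flat background with a
minimum center distance, and corrupts them with either noise model.
SNR is defined as `var(clean - background) / sigma_n^2` — a regime where
noise power is a hundred times the signal's corresponds to SNR 0.01 in this
convention; the reference studies run at 0.5 (detection) and 0.1
(denoising).

Desk-scale reference studies (one CPU core, minutes each): 6 micrographs of
128^2, 22 particles of radius 6 px each, 10% labeled (13 clicks total),
`pi ~ 0.152`; training 300 iterations (150 at SNR 0.1), patch 48, batch 4,
base channels 16. The flat-noise recovery study uses 8 micrographs of 128^2
so the pixel count dominates network capacity. Results under these
conditions: detection F1 1.0 at threshold 0.5 (match radius 3 px = half the
particle radius), denoising gain ~15-20 dB, noise std recovered to ~0.1%.

What these studies do *not* show: real micrographs have structured
backgrounds (ice gradients, carbon edges, contamination), CTF-correlated
noise, overlapping and heterogeneous particles, and annotation errors —
none of which the generator emulates. Passing the synthetic studies
validates the machinery (the architecture contract, the closed forms, the
PU objective, the optimization), not real-data picking performance. No CTF
simulation, movie frames, or tilt geometry; no 3-D reconstruction beyond
the FSC utility.
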