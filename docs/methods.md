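# Methods

## Problem and measurement model

Accelerated multi-coil MRI is the linear inverse problem `y = P F S x + eta`:
the complex image `x` is weighted by each receiver coil's complex
sensitivity profile (`S`), Fourier-transformed per coil (`F`, centered
orthonormal convention), subsampled along the phase-encode direction (`P`,
acceleration factor `R`), and corrupted by complex Gaussian thermal noise
`eta` that is correlated across coils with covariance `C` and independent
across k-space locations.  With unit-RSS ("root-sum-of-squares") maps and
full sampling, `A = F S` is an isometry, so `A^H A = I`; this exactness is
what the operator tests pin down against dense matrices built from an
explicit centered DFT.

Training data are *noisy but fully sampled* scans.  The package's goal is
learning image priors from such data without clean references, then using
them for accelerated (undersampled) reconstruction.

## Preprocessing: whitening, normalization, SNR

Raw multi-coil noise is made white by mapping every k-space coil vector
through `L^{-1}`, where `C = L L^H` is estimated from signal-free
image-domain corner patches (four patches, each a quarter of the grid side
by default — the synthetic phantoms keep their corners empty by
construction so this assumption is exact in tests).  Whitening mixes coils,
so sensitivity maps are transformed with the same `L^{-1}` and re-normalized
to unit RSS; the spatial RSS weight is absorbed into the reference image.

Intensity is normalized by the 99th percentile of the RSS image
reconstructed from the zero-padded central ACS block (24x24 at clinical
matrix sizes; 8x8 for the 32x32 desk-scale grids).  After both steps the
noise is white with known complex variance `sigma^2` and the dataset SNR is
`10 log10(1 / sigma^2)` dB.  Lower SNRs are simulated by adding white
complex noise of variance `10^(-SNR/10) - sigma^2` — valid precisely because
variances of independent Gaussians add.  The simulator's base noise level
(`noise_base_std = 0.0125` per coil before whitening) was chosen so that the
synthetic native SNR lands near 30 dB, the same regime as clinical
brain data; lower-SNR conditions are always produced by the
noise-addition path, never by re-simulating.

## Stage 1 — self-supervised denoising (GSURE)

A denoiser `g_phi` maps the scaled adjoint `u = A^H y / sigma_r^2` to a
clean coil-combined image, where `sigma_r^2` is the per-real-component noise
variance (half the complex variance).  Without ground truth it is trained on
the generalized SURE objective

    L = ||g(u)||^2 + 2 div_u g(u) - 2 Re<g(u), A^+ y>,

whose expectation over the noise equals `E||g(u) - x||^2 - ||x||^2`.  The
factor-of-two bookkeeping between complex variance and real-composite
coordinates matters: with the complex variance in the input scaling the
divergence coefficient would be 1, with the per-real-component variance it
is 2.  The implementation uses the latter convention and verifies it with a
10^4-draw Monte-Carlo oracle (agreement well within 1%).

The divergence is estimated with a single fresh Gaussian probe per loss
evaluation, `div ~= <b, g(x + eps b) - g(x)>/eps` with `eps = 0.001`
(exact for linear maps at any `eps`; bias vanishing as `eps -> 0`
otherwise).  Because the `1/sigma_r^2` input scaling explodes at high SNR,
the network consumes `u * sigma_r^2` (the raw adjoint) by default; probing
in `u`-space automatically accounts for the chain rule, so the loss is
unchanged.

Two denoiser parameterizations exist: a small residual conv-net (default;
zero-initialized last layer makes it the identity at initialization) and an
explicit linear map over real-composite coordinates for oracle tests.  The
linear mode supports full-matrix and diagonal structure; the diagonal form
is the statistically meaningful oracle for isotropic Gaussian
signal-plus-noise, where the MMSE (Wiener) filter is a multiple of the
identity — an unconstrained 128x128 map cannot be pinned to a few percent
in operator norm with any realistic sample count.

## Stage 2a — diffusion prior and posterior sampling

The score model predicts `E[x0 | xt]` for `xt = x0 + sigma eta` and is
trained with the EDM formulation: log-normal noise-level draws
(location -1.2, scale 1.2, clipped to [0.002, 80]), `sigma`-dependent
preconditioning (`c_skip`, `c_out`, `c_in`, `c_noise = ln(sigma)/4`,
`sigma_data = 0.5`) and the weighting that makes the effective per-level
loss uniform.  The noise embedding enters as a constant third input
channel.

Sampling discretizes the reverse-time variance-exploding SDE by its exact
Gaussian (ancestral) transition between consecutive grid levels, which
keeps the per-level marginals exact for any schedule — validated by
matching the first two moments of a fully analytic Gaussian prior within
Monte-Carlo error.  The final output is the clean-image prediction at the
last level, removing the residual `sigma_min` noise.  The default inference
schedule is 500 linear steps on [0.004, 10] (100 steps in the desk-scale
experiment presets); the training and inference `sigma_max` differ by
design.

Posterior sampling (DPS) subtracts, at each step, the guidance gradient of
`0.5 ||y - A x0_hat(x)||^2` with respect to the current state
(back-propagated through the network), scaled by
`gamma_t = gamma_0 / ||y - A x0_hat||`.  On a 16x16 linear-Gaussian
problem with a dense conjugate-posterior oracle, `gamma_0 = 1` is
measurably under-guided (~25% posterior-mean bias) while `gamma_0` in
[3, 5] brings the 200-sample DPS mean within 10% of the exact posterior
mean; the experiment presets therefore use `gamma_0 = 5`, calibrated once
on that oracle, while the bare `DpsConfig` default stays at 1.0.  Point
estimates average several posterior samples (five in the clinical-scale
protocol; two to three in desk-scale presets), and the per-pixel variance
across samples is returned as an uncertainty map.

## Stage 2b — unrolled reconstruction (MoDL)

The unrolled network alternates a conjugate-gradient data-consistency
solve `argmin_x ||y - Ax||^2 + lam ||x - z||^2` with a small shared
residual denoiser, for 6 unrolls starting from `A^H y`, and is trained
end-to-end with the NRMSE objective `||x_ref - x_hat|| / ||x_ref||`.
Since the DC solve is linear in `z` for fixed `lam`, its exact adjoint is
`lam (A^H A + lam I)^{-1}` — one extra CG solve — so gradients are implicit
rather than differentiated through CG iterations; `d/d lam` uses
`M^{-1}(z - x_out)` with the same solve.  `lam` is a single scalar trained
as `exp(log_lam)`, initialized at 1.

## Neural-network substrate

All networks are small convolutional stacks (3x3 kernels, ReLU, 16-24
hidden channels, ~10-30k parameters) on two real channels (real/imaginary
parts), implemented in a purpose-built numpy layer framework with explicit
forward/backward passes and Adam.  The functional layer design (caches
returned per call) makes the multiple concurrent forward passes required by
divergence probing and unrolling trivially correct; all gradients are
verified against central finite differences.  Float64 is used throughout
for determinism and conditioning.  Training supports a linear
learning-rate decay, which is what lets the stochastic GSURE objective
settle to a few-percent neighborhood of closed-form optima.

## Synthetic data

Phantoms are sums of random overlapping ellipses (piecewise-smooth
magnitude, at least three distinct levels for several shapes) with a smooth
low-order polynomial phase; all ellipses are confined to the central disc
so corners are signal-free.  Coil maps are Gaussian magnitude bumps
centered at distinct border angles with gentle linear phase ramps, a smooth
stand-in for estimated (ESPIRiT-like) maps.  What the generator does *not*
emulate: anatomical texture and fine structure, 3D volumes, motion and
eddy-current artifacts, non-Gaussian or spatially varying noise, and map
estimation error.  Passing tests therefore demonstrate the statistical and
numerical correctness of the pipeline and the direction of its benefits on
piecewise-smooth images — not clinical image quality.

## Experiment protocol and problem sizes

The desk-scale study point mirrors the low-SNR cell of the clinical
protocol: 32x32 grids, 4 coils, training and inference SNR of 12 dB,
R = 4 with 6 fully sampled ACS lines.  Each training SNR gets its own
GSURE denoiser; priors and MoDL networks are trained twice, on noisy
adjoints ("naive") and on denoised images ("gsure"); every method is
scored per (training SNR, inference SNR, R) cell with masked NRMSE / SSIM
(7x7 Gaussian window, K1 = 0.01, K2 = 0.03, data range = masked reference
maximum) / PSNR (masked reference peak), and naive-vs-gsure differences are
tested per metric with the paired Wilcoxon signed-rank test under
Bonferroni correction across the whole grid.  The acceptance runs use 60
training and 20-50 test cases with tiny networks; these sizes are the
package's deliberate desk-scale choice and scale up through the config
without code changes.  The anatomy mask is reference magnitude above 10% of
its 99th percentile with hole filling.  Synthetic evaluation references are
the ground-truth phantoms (the clinical protocol substitutes native-SNR
scans, which biases metrics at low SNR; with simulation the unbiased
reference is available).

## Known limitations

- DPS guidance uses the residual-normalized heuristic; it is biased for
  weak guidance and the calibrated strength transfers across the tested
  regime but is not adaptive.
- The GSURE stage assumes exactly white, known-variance noise; covariance
  estimation error propagates unexamined.
- Caching in the experiment runner is keyed by config hash only; editing
  code without changing the config reuses stale stage outputs in an
  existing run directory.
- Tiny networks under-fit rich image content by design; absolute NRMSE
  numbers are not comparable to clinical-scale results, only the
  comparisons between training strategies are.
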