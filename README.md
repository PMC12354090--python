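# gsuremri

Robust multi-coil MRI reconstruction from **noisy** training data, via a
two-stage pipeline:

1. **Self-supervised denoising.**  A denoiser `g_phi` is trained on noisy,
   fully sampled, pre-whitened k-space with the generalized SURE loss

   ```
   L = ||g(u)||^2 + 2 div_u g(u) - 2 Re<g(u), A^+ y>,    u = A^H y / sigma_r^2
   ```

   which is an unbiased estimate of the supervised MSE up to a constant —
   no clean images needed.  The divergence is estimated with a single
   Gaussian probe per step.

2. **Reconstruction networks trained on the denoised images.**  Two
   families: a diffusion prior (EDM-style `E[x0|xt]` predictor) used with
   diffusion posterior sampling (DPS) and posterior averaging, and an
   unrolled MoDL network alternating conjugate-gradient data consistency
   with a learned denoiser.  Each is compared against the same model
   trained directly on noisy data ("naive" vs "gsure" variants).

The package is aimed at researchers studying learning-based MRI
reconstruction when training scans are noisy (low field, high acceleration,
fast protocols).  Everything is exercised at desk scale on a built-in
synthetic generator (random-ellipse phantoms, smooth coil maps,
coil-correlated complex Gaussian noise), so every stage runs and is tested
on a laptop CPU; the same code reads fastMRI-style HDF5 k-space
(`dataset "kspace"`, slice x coil x kx x ky).

Supporting machinery: the SENSE operator `A = P F S` with exact adjoint /
CG normal-equation solver / pseudo-inverse, noise pre-whitening from
covariance estimates, ACS-percentile intensity normalization with the SNR
convention `SNR = 10 log10(1/sigma^2)` dB, masked NRMSE/SSIM/PSNR metrics
and paired Wilcoxon significance testing, plus a tiny numpy neural-network
substrate with verified gradients (no GPU framework required).

## Worked example

```python
import numpy as np
from gsuremri.synth import make_phantom, make_coil_maps, NoiseSpec, simulate_kspace
from gsuremri.forward_model import SenseOperator, MultiCoilKSpace, apply_adjoint
from gsuremri import preprocess as pp
from gsuremri.gsure import make_gsure_sample, train_denoiser, GsureTrainConfig
from gsuremri.modl import nrmse_loss

# noisy, fully sampled multi-coil scans of random-ellipse phantoms
samples, truths, adjoints = [], [], []
for i in range(40):
    ph = make_phantom((32, 32), 5, seed=2 * i)
    maps = make_coil_maps((32, 32), 4, seed=2 * i + 1)
    ks = simulate_kspace(ph, maps, NoiseSpec(coil_covariance=np.zeros((4, 4)), seed=i))
    noisy = pp.add_noise_to_snr(
        MultiCoilKSpace(data=ks.data, noise_sigma=1e-9), target_snr=12.0, seed=100 + i)
    op = SenseOperator(maps=maps)
    samples.append(make_gsure_sample(noisy, op))
    truths.append(ph.image)
    adjoints.append(apply_adjoint(op, noisy))

model = train_denoiser(samples, GsureTrainConfig(epochs=20, hidden=16, seed=0))
from gsuremri.gsure import denoise_dataset
denoised = denoise_dataset(model, samples)
print("adjoint  NRMSE:", np.mean([nrmse_loss(a, x) for a, x in zip(adjoints, truths)]))
print("denoised NRMSE:", np.mean([nrmse_loss(d, x) for d, x in zip(denoised, truths)]))
```

Output (fixed seeds):

```
adjoint  NRMSE: 1.4159566128369732
denoised NRMSE: 0.8355884198465262
```

At 12 dB the self-supervised denoiser — trained with no access to the
ground-truth phantoms — removes roughly 40% of the error of the raw
coil-combined adjoint.  The full naive-vs-gsure comparison matrix (both reconstruction
families, any grid of training/inference SNRs and accelerations) runs with:

```
gsure-mri run -o runs/toy            # built-in toy preset
gsure-mri run -c my_config.yaml -o runs/exp
```

which writes `report.csv` (per-case masked NRMSE/SSIM/PSNR),
`paired_tests.csv` (Wilcoxon, Bonferroni-corrected), `speed_curve.csv`
(NRMSE vs number of averaged posterior samples) and `summary.txt`.

## Layout

- `gsuremri.synth` — phantoms, coil maps, noisy k-space simulation, HDF5 writer
- `gsuremri.forward_model` — SENSE operator, masks, CG solvers, HDF5 reader
- `gsuremri.preprocess` — covariance estimation, pre-whitening, ACS normalization, SNR
- `gsuremri.gsure` — GSURE loss, Monte-Carlo divergence, denoiser training
- `gsuremri.diffusion_prior` — EDM training, ancestral sampler, DPS, posterior averaging
- `gsuremri.modl` — data-consistency block, unrolled network, NRMSE training
- `gsuremri.evaluation` — anatomy masks, metrics, paired Wilcoxon reports
- `gsuremri.pipeline` / `gsuremri.cli` — experiment DAG with cached stages, `gsure-mri` CLI

See `docs/methods.md` for the model conventions, calibration choices and
limitations.
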