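"""Self-supervised MMSE denoising via the generalized SURE loss.

A denoiser g_phi maps the scaled adjoint image u = A^H y / sigma_r^2 (with
sigma_r^2 the per-real-component noise variance, i.e. half the complex
variance) to a clean coil-combined image.  Without ground truth, g_phi is
trained with the GSURE objective

    L(u) = ||g(u)||^2 + 2 div_u g(u) - 2 Re<g(u), A^+ y>,

whose expectation over the noise equals the supervised quadratic loss
||g(u) - x||^2 up to the constant ||x||^2.  The divergence is taken on the
real-composite representation (real and imaginary parts as independent
coordinates) and estimated with a single Gaussian probe per evaluation:

    div g(x) ~= <b, g(x + eps b) - g(x)> / eps,   b ~ N(0, I).

Because 1/sigma_r^2 input scaling is badly conditioned at high SNR, the
network may consume u multiplied back by sigma_r^2 (i.e. the raw adjoint);
the probe-based divergence accounts for that gain automatically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import h5py
import numpy as np

from ._nn import Adam, Residual, init_conv_net

__all__ = [
    "DenoiserModel",
    "GsureSample",
    "GsureTrainConfig",
    "make_gsure_sample",
    "mc_divergence",
    "gsure_loss",
    "supervised_loss",
    "train_denoiser",
    "denoise_dataset",
    "save_denoised",
]


def c2r(x: np.ndarray) -> np.ndarray:
    """Complex (H, W) -> real channels (2, H, W)."""
    return np.stack([x.real, x.imag])


def r2c(xr: np.ndarray) -> np.ndarray:
    """Real channels (2, H, W) -> complex (H, W)."""
    return xr[0] + 1j * xr[1]


def real_dot(a: np.ndarray, b: np.ndarray) -> float:
    """Real-composite inner product of two complex arrays."""
    return float(np.sum(a.real * b.real + a.imag * b.imag))


@dataclass(frozen=True)
class GsureSample:
    """One training sample: network input, pseudo-inverse image, noise level.

    ``sigma_sq`` is the complex noise variance of the whitened+normalized
    measurements; ``u`` is A^H y divided by sigma_sq / 2 (per-real-component
    variance), the scaling under which the GSURE identity holds.
    """

    u: np.ndarray
    pinv: np.ndarray
    sigma_sq: float

    def __post_init__(self) -> None:
        if self.u.shape != self.pinv.shape:
            raise ValueError("u and pinv must share a shape")
        if self.sigma_sq <= 0:
            raise ValueError("sigma_sq must be positive")

    @property
    def sigma_r_sq(self) -> float:
        """Per-real-component noise variance (half the complex variance)."""
        return self.sigma_sq / 2.0


def make_gsure_sample(kspace, op) -> GsureSample:
    """Build a GSURE sample from whitened+normalized k-space and its operator."""
    from .forward_model import apply_adjoint, pseudo_inverse

    sigma_sq = float(kspace.noise_sigma)
    adj = apply_adjoint(op, kspace)
    if op.mask is None and op.maps.normalized:
        pinv = adj  # A is an isometry: A^+ = A^H
    else:
        pinv = pseudo_inverse(op, kspace)
    return GsureSample(u=adj / (sigma_sq / 2.0), pinv=pinv, sigma_sq=sigma_sq)


class DenoiserModel:
    """Parametric denoiser g_phi on coil-combined complex images.

    Two modes: a small residual convolutional network (the default), or an
    explicit real-composite linear map (test/oracle mode, whose divergence is
    exactly the trace of its matrix).

    ``standardize`` rescales the network input by the per-sample
    sigma_r^2, so the network effectively sees the raw adjoint image.
    """

    def __init__(self, shape: tuple[int, int], mode: str = "network", *,
                 hidden: int = 24, n_hidden: int = 2, standardize: bool = True,
                 linear_structure: str = "full", seed: int = 0) -> None:
        self.shape = shape
        self.mode = mode
        self.standardize = standardize
        self.linear_structure = linear_structure
        rng = np.random.default_rng(seed)
        if mode == "network":
            self.net = Residual(init_conv_net(2, 2, hidden, n_hidden, rng,
                                              zero_last=True))
            self.params = self.net.params
        elif mode == "linear":
            n = 2 * shape[0] * shape[1]
            if linear_structure == "full":
                self.weight = np.eye(n)
            elif linear_structure == "diagonal":
                self.weight = np.ones(n)
            else:
                raise ValueError(f"unknown linear structure {linear_structure!r}")
            self.params = [self.weight]
        else:
            raise ValueError(f"unknown mode {mode!r}")

    # -- low-level real-composite interface (used by the trainer) ----------
    def forward_real(self, xr: np.ndarray):
        if self.mode == "network":
            y, cache = self.net.forward(xr[None])
            return y[0], cache
        flat = xr.reshape(-1)
        if self.linear_structure == "diagonal":
            return (self.params[0] * flat).reshape(xr.shape), flat
        return (self.params[0] @ flat).reshape(xr.shape), flat

    def backward_real(self, cache, gy: np.ndarray):
        if self.mode == "network":
            gx, grads = self.net.backward(cache, gy[None])
            return gx[0], grads
        flat = cache
        gflat = gy.reshape(-1)
        if self.linear_structure == "diagonal":
            return (self.params[0] * gflat).reshape(gy.shape), [gflat * flat]
        return (self.params[0].T @ gflat).reshape(gy.shape), [np.outer(gflat, flat)]

    # -- user-facing complex interface --------------------------------------
    def gain(self, sample_sigma_r_sq: float) -> float:
        return sample_sigma_r_sq if self.standardize else 1.0

    def apply(self, x: np.ndarray, gain: float = 1.0) -> np.ndarray:
        """g(x): complex in, complex out; ``gain`` rescales the net input."""
        out, _ = self.forward_real(c2r(x * gain))
        return r2c(out)

    def as_callable(self, gain: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
        return lambda x: self.apply(x, gain)

    def exact_divergence(self, gain: float = 1.0) -> float:
        """Trace of the real-composite Jacobian (linear mode only)."""
        if self.mode != "linear":
            raise ValueError("exact divergence available only in linear mode")
        if self.linear_structure == "diagonal":
            return float(np.sum(self.params[0])) * gain
        return float(np.trace(self.params[0])) * gain


def mc_divergence(g: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
                  eps: float = 0.001, probe_seed: int | None = None,
                  rng: np.random.Generator | None = None) -> float:
    """Single-probe Monte-Carlo divergence on the real-composite coordinates.

    Unbiased for linear maps at any eps (the difference quotient is exact);
    for smooth nonlinear maps the bias vanishes as eps -> 0.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if rng is None:
        rng = np.random.default_rng(probe_seed)
    b = rng.standard_normal(x.shape) + 1j * rng.standard_normal(x.shape)
    return real_dot(b, g(x + eps * b) - g(x)) / eps


def gsure_loss(g: Callable[[np.ndarray], np.ndarray], sample: GsureSample,
               eps: float = 0.001, probe_seed: int | None = None,
               rng: np.random.Generator | None = None) -> float:
    """The self-supervised loss; never touches the ground truth."""
    out = g(sample.u)
    div = mc_divergence(g, sample.u, eps=eps, probe_seed=probe_seed, rng=rng)
    return float(np.sum(np.abs(out) ** 2)) + 2.0 * div \
        - 2.0 * real_dot(out, sample.pinv)


def supervised_loss(g: Callable[[np.ndarray], np.ndarray], sample: GsureSample,
                    truth: np.ndarray) -> float:
    """Oracle loss 0.5 ||g(u) - x||^2 (synthetic/test mode only)."""
    return 0.5 * float(np.sum(np.abs(g(sample.u) - truth) ** 2))


@dataclass
class GsureTrainConfig:
    epochs: int = 40
    lr: float = 1e-3
    lr_decay: bool = True  # linear decay to zero over training
    eps: float = 0.001  # Monte-Carlo divergence probe step
    batch_size: int = 4
    seed: int = 0
    hidden: int = 24
    n_hidden: int = 2
    standardize: bool = True
    mode: str = "network"
    linear_structure: str = "full"
    verbose: bool = False


def train_denoiser(dataset: Sequence[GsureSample],
                   config: GsureTrainConfig | None = None) -> DenoiserModel:
    """Minimize the mean GSURE loss by Adam with one fresh probe per step.

    Per-sample parameter gradient: with v the (optionally standardized)
    network input, backpropagate upstream 2 g(u) - 2 pinv - (2/eps) b at v
    and upstream (2/eps) b at v + eps * gain * b, and sum.
    """
    if config is None:
        config = GsureTrainConfig()
    if not dataset:
        raise ValueError("dataset must be non-empty")
    shape = dataset[0].u.shape
    model = DenoiserModel(shape, mode=config.mode, hidden=config.hidden,
                          n_hidden=config.n_hidden,
                          standardize=config.standardize,
                          linear_structure=config.linear_structure,
                          seed=config.seed)
    opt = Adam(model.params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    n = len(dataset)
    history = []
    for epoch in range(config.epochs):
        if config.lr_decay:
            opt.lr = config.lr * (1.0 - epoch / config.epochs)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = [dataset[i] for i in order[start:start + config.batch_size]]
            grads = [np.zeros_like(p) for p in model.params]
            loss = 0.0
            for s in batch:
                gain = model.gain(s.sigma_r_sq)
                v = c2r(s.u * gain)
                b = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
                br = c2r(b)
                out1, cache1 = model.forward_real(v)
                out2, cache2 = model.forward_real(v + config.eps * gain * br)
                g_u = r2c(out1)
                div = real_dot(b, r2c(out2) - g_u) / config.eps
                loss += float(np.sum(np.abs(g_u) ** 2)) + 2.0 * div \
                    - 2.0 * real_dot(g_u, s.pinv)
                up1 = 2.0 * out1 - 2.0 * c2r(s.pinv) - (2.0 / config.eps) * br
                up2 = (2.0 / config.eps) * br
                for target, cache, up in ((grads, cache1, up1),
                                          (grads, cache2, up2)):
                    _, g = model.backward_real(cache, up)
                    for acc, gi in zip(target, g):
                        acc += gi
            for acc in grads:
                acc /= len(batch)
            loss /= len(batch)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"GSURE loss diverged (epoch {epoch}): {loss}")
            opt.step(grads)
            epoch_loss += loss
        history.append(epoch_loss / max(1, -(-n // config.batch_size)))
        if config.verbose:
            print(f"[gsure] epoch {epoch + 1}/{config.epochs} "
                  f"loss {history[-1]:.4f}")
    model.history = history
    return model


def denoise_dataset(model: DenoiserModel,
                    dataset: Sequence[GsureSample]) -> list[np.ndarray]:
    """Apply the trained denoiser to every sample, preserving order."""
    out = []
    for s in dataset:
        if s.u.shape != model.shape:
            raise ValueError("sample shape does not match the model")
        out.append(model.apply(s.u, model.gain(s.sigma_r_sq)))
    return out


def save_denoised(path, images: Sequence[np.ndarray]) -> None:
    """Stage-1 output archive: dataset 'denoised', (n, Nx, Ny) complex64."""
    with h5py.File(path, "w") as f:
        f.create_dataset("denoised",
                         data=np.stack(images).astype(np.complex64))
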