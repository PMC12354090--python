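"""Noise pre-whitening, ACS intensity normalization and SNR adjustment.

The raw measurement model is y = F S x + eta with eta zero-mean complex
Gaussian, correlated across coils with covariance C.  Preprocessing maps this
to y* = F S x* + eta* where eta* is white with a known scalar complex
variance sigma^2:

1. estimate C from signal-free image-domain corner patches,
2. pre-whiten every k-space coil vector through L^{-1} where C = L L^H
   (unit complex variance per coil afterwards),
3. divide k-space by the 99th percentile of the root-sum-of-squares image
   reconstructed from the zero-padded central ACS block.

After step 3 the noise variance is 1/scale^2 and the dataset SNR is defined
as 10 log10(1 / sigma^2) in dB.  Additional white noise can then be added to
reach any lower target SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fft import ifft2c
from .forward_model import MultiCoilKSpace

__all__ = [
    "WhiteningTransform",
    "NormalizationRecord",
    "estimate_noise_covariance",
    "prewhiten",
    "acs_normalize",
    "snr_db",
    "target_sigma_sq",
    "add_noise_to_snr",
]


@dataclass(frozen=True)
class WhiteningTransform:
    """Cholesky whitening: coil vectors are mapped through L^{-1}, C = L L^H."""

    covariance: np.ndarray
    cholesky_factor: np.ndarray

    @classmethod
    def from_covariance(cls, cov: np.ndarray) -> "WhiteningTransform":
        cov = np.asarray(cov, dtype=complex)
        w = np.linalg.eigvalsh(cov)
        if w.min() <= 1e-12 * max(1.0, float(w.max())):
            raise ValueError(
                f"covariance is singular: smallest eigenvalue {w.min():.3e}")
        return cls(covariance=cov, cholesky_factor=np.linalg.cholesky(cov))

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Whiten (Nc, ...) data along the coil axis."""
        from scipy.linalg import solve_triangular

        flat = data.reshape(data.shape[0], -1)
        white = solve_triangular(self.cholesky_factor, flat, lower=True)
        return white.reshape(data.shape)


@dataclass(frozen=True)
class NormalizationRecord:
    """ACS-based intensity scale and the resulting dataset SNR."""

    scale: float
    acs_width: int
    snr_db: float


def estimate_noise_covariance(kspace: MultiCoilKSpace,
                              patch: int = 32) -> np.ndarray:
    """Sample coil covariance from image-domain corner patches.

    The orthonormal IFFT of stationary k-space noise preserves the coil
    covariance, and the corners of the coil images are signal-free for the
    synthetic generator (air in real scans).  Returns a Hermitian PSD
    Nc x Nc matrix in complex-variance units.
    """
    nc = kspace.n_coils
    nx, ny = kspace.shape
    patch = min(patch, nx // 2, ny // 2)
    n_samples = 4 * patch * patch
    if n_samples < 2 * nc:
        raise ValueError(
            f"corner patches give {n_samples} samples; need >= {2 * nc}")
    coil_images = ifft2c(kspace.data)
    corners = [coil_images[:, :patch, :patch], coil_images[:, :patch, -patch:],
               coil_images[:, -patch:, :patch], coil_images[:, -patch:, -patch:]]
    samples = np.concatenate([c.reshape(nc, -1) for c in corners], axis=1)
    samples = samples - samples.mean(axis=1, keepdims=True)
    cov = samples @ samples.conj().T / samples.shape[1]
    return (cov + cov.conj().T) / 2


def prewhiten(kspace: MultiCoilKSpace, cov: np.ndarray) -> MultiCoilKSpace:
    """Map every k-space coil vector through L^{-1}; output noise is CN(0, I)."""
    transform = WhiteningTransform.from_covariance(cov)
    white = transform.apply(kspace.data)
    return MultiCoilKSpace(data=white, mask=kspace.mask, noise_sigma=1.0)


def acs_normalize(kspace: MultiCoilKSpace, acs: int = 24,
                  pct: float = 99.0) -> tuple[MultiCoilKSpace, NormalizationRecord]:
    """Normalize by the ``pct``-th percentile of the ACS RSS reconstruction.

    The central ``acs x acs`` k-space block is zero-padded back to the full
    grid, inverse-transformed per coil and combined by root-sum-of-squares;
    the chosen percentile of that image's magnitude is the scale.
    """
    nx, ny = kspace.shape
    if acs > min(nx, ny):
        raise ValueError("ACS block larger than the grid")
    lox, loy = nx // 2 - acs // 2, ny // 2 - acs // 2
    padded = np.zeros_like(kspace.data)
    padded[:, lox:lox + acs, loy:loy + acs] = \
        kspace.data[:, lox:lox + acs, loy:loy + acs]
    rss = np.sqrt(np.sum(np.abs(ifft2c(padded)) ** 2, axis=0))
    scale = float(np.percentile(rss, pct))
    if scale <= 0:
        raise ValueError("ACS region is all zero; cannot normalize")
    sigma_in = kspace.noise_sigma if np.isscalar(kspace.noise_sigma) else None
    sigma_sq = (sigma_in / scale ** 2) if sigma_in is not None else None
    record = NormalizationRecord(
        scale=scale, acs_width=acs,
        snr_db=snr_db(sigma_sq) if sigma_sq else float("nan"))
    out = MultiCoilKSpace(data=kspace.data / scale, mask=kspace.mask,
                          noise_sigma=sigma_sq)
    return out, record


def snr_db(sigma_sq: float) -> float:
    """SNR in dB of a whitened+normalized dataset: 10 log10(1 / sigma^2)."""
    if sigma_sq <= 0:
        raise ValueError("sigma_sq must be positive")
    return 10.0 * np.log10(1.0 / sigma_sq)


def target_sigma_sq(snr: float) -> float:
    """Noise complex variance giving the requested SNR in dB."""
    return float(10.0 ** (-snr / 10.0))


def add_noise_to_snr(kspace: MultiCoilKSpace, target_snr: float,
                     seed: int) -> MultiCoilKSpace:
    """Add white complex noise to drive a whitened dataset down to target SNR.

    Valid only because the input noise is already white: independent Gaussian
    variances add, so the increment has variance 10^(-target/10) - sigma^2.
    """
    if not np.isscalar(kspace.noise_sigma):
        raise ValueError("add_noise_to_snr requires whitened data "
                         "(scalar noise_sigma)")
    current = float(kspace.noise_sigma)
    target = target_sigma_sq(target_snr)
    extra = target - current
    if extra < -1e-15:
        raise ValueError(
            f"target SNR {target_snr:.2f} dB is above the current "
            f"{snr_db(current):.2f} dB; noise cannot be removed")
    if extra <= 0:
        return MultiCoilKSpace(data=kspace.data.copy(), mask=kspace.mask,
                               noise_sigma=current)
    rng = np.random.default_rng(seed)
    shape = kspace.data.shape
    eta = np.sqrt(extra / 2.0) * (rng.standard_normal(shape)
                                  + 1j * rng.standard_normal(shape))
    if kspace.mask is not None:
        eta = eta * kspace.mask.pattern
    return MultiCoilKSpace(data=kspace.data + eta, mask=kspace.mask,
                           noise_sigma=target)
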