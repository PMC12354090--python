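"""Synthetic multi-coil data with the statistical structure the pipeline assumes.

The generator emulates what the real pipeline consumes: piecewise-smooth
complex anatomy (overlapping ellipses with a smooth low-order polynomial
phase), spatially smooth complex coil sensitivity profiles, and additive
complex Gaussian k-space noise with an arbitrary coil covariance matrix.

Ellipse extents are constrained to the central disc of the field of view so
the image corners are signal-free by construction — the corner patches used
for noise-covariance estimation are then guaranteed noise-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from ._fft import fft2c

__all__ = [
    "Phantom",
    "CoilMaps",
    "NoiseSpec",
    "make_phantom",
    "make_coil_maps",
    "simulate_kspace",
    "write_kspace_h5",
]


@dataclass(frozen=True)
class Phantom:
    """Ground-truth complex image plus its support mask."""

    image: np.ndarray
    support_mask: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.image)):
            raise ValueError("phantom image must be finite")


@dataclass(frozen=True)
class CoilMaps:
    """Complex coil sensitivities, (Nc, Nx, Ny).

    When ``normalized`` the per-pixel root-sum-of-squares over coils is 1,
    which makes the fully sampled SENSE operator an isometry.
    """

    maps: np.ndarray
    normalized: bool

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


@dataclass(frozen=True)
class NoiseSpec:
    """Coil noise covariance (complex variance units) and the draw seed."""

    coil_covariance: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        c = np.asarray(self.coil_covariance)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("coil_covariance must be square")
        if np.max(np.abs(c - c.conj().T)) > 1e-12:
            raise ValueError("coil_covariance must be Hermitian (tol 1e-12)")
        w = np.linalg.eigvalsh(c)
        if w.min() < -1e-12 * max(1.0, w.max()):
            raise ValueError("coil_covariance must be positive semidefinite")


def make_phantom(shape: tuple[int, int], n_shapes: int, seed: int) -> Phantom:
    """Piecewise-smooth magnitude from overlapping ellipses, smooth phase.

    Ellipses are confined to the central disc (radius <= 0.7 in normalized
    coordinates), keeping the field-of-view corners signal-free.
    """
    nx, ny = shape
    if nx < 16 or ny < 16:
        raise ValueError("shape must be at least 16 x 16")
    if n_shapes < 1:
        raise ValueError("n_shapes must be >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx))
    mag = np.zeros(shape)
    for _ in range(n_shapes):
        cx, cy = rng.uniform(-0.35, 0.35, size=2)
        a, b = rng.uniform(0.10, 0.35, size=2)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(0.3, 1.0)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mag += amp * ((u / a) ** 2 + (v / b) ** 2 <= 1.0)
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    support = mag > 0
    coeffs = rng.uniform(-0.5, 0.5, size=6)
    phase = (coeffs[0] + coeffs[1] * xx + coeffs[2] * yy
             + coeffs[3] * xx * yy + coeffs[4] * xx ** 2 + coeffs[5] * yy ** 2)
    image = mag * np.exp(1j * np.pi * phase)
    return Phantom(image=image, support_mask=support)


def make_coil_maps(shape: tuple[int, int], n_coils: int, seed: int,
                   normalize: bool = True) -> CoilMaps:
    """Smooth Gaussian-bump coil profiles centered on the FOV border.

    Each coil gets a magnitude bump at a distinct border angle and a gentle
    linear phase ramp — an idealised stand-in for estimated (e.g. ESPIRiT)
    sensitivity maps.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    nx, ny = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx))
    maps = np.empty((n_coils, nx, ny), dtype=complex)
    angle0 = rng.uniform(0, 2 * np.pi)
    for c in range(n_coils):
        ang = angle0 + 2 * np.pi * c / n_coils
        cx, cy = 1.1 * np.cos(ang), 1.1 * np.sin(ang)
        width = rng.uniform(0.9, 1.3)
        bump = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * width ** 2))
        slope = rng.uniform(-0.5, 0.5, size=2)
        phase = np.pi * (slope[0] * xx + slope[1] * yy) + rng.uniform(0, 2 * np.pi)
        maps[c] = bump * np.exp(1j * phase)
    if normalize:
        rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
        maps = np.where(rss > 0, maps / rss, 0.0)
    return CoilMaps(maps=maps, normalized=normalize)


def draw_coil_noise(noise: NoiseSpec, shape: tuple[int, int],
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Complex Gaussian (Nc, Nx, Ny) noise with the requested coil covariance.

    Convention: entry C[i, i] is the complex variance of coil i (real and
    imaginary parts each carry C[i, i] / 2), matching the MRI thermal-noise
    model.
    """
    c = np.asarray(noise.coil_covariance, dtype=complex)
    n_coils = c.shape[0]
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    # PSD square root via eigendecomposition (allows singular covariances).
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 0.0, None)
    sqrt_c = v * np.sqrt(w)
    z = (rng.standard_normal((n_coils,) + shape)
         + 1j * rng.standard_normal((n_coils,) + shape)) / np.sqrt(2.0)
    return np.einsum("ij,jxy->ixy", sqrt_c, z)


def simulate_kspace(phantom: Phantom, maps: CoilMaps, noise: NoiseSpec,
                    mask=None):
    """y = P F S x + eta: noisy (optionally undersampled) multi-coil k-space.

    Noise is correlated across coils per ``noise.coil_covariance`` and
    independent across k-space locations; the result is deterministic given
    ``noise.seed``.
    """
    from .forward_model import MultiCoilKSpace  # local import breaks the cycle

    if phantom.image.shape != maps.maps.shape[-2:]:
        raise ValueError("phantom and coil maps have inconsistent grids")
    ks = fft2c(maps.maps * phantom.image)
    eta = draw_coil_noise(noise, phantom.image.shape)
    y = ks + eta
    if mask is not None:
        y = y * mask.pattern
    return MultiCoilKSpace(data=y, mask=mask,
                           noise_sigma=np.asarray(noise.coil_covariance))


def write_kspace_h5(path, volume: np.ndarray) -> None:
    """Write k-space in the fastMRI-style dialect.

    ``volume`` is (n_slices, Nc, Nx, Ny) complex; stored as complex64 under
    the dataset name "kspace".
    """
    vol = np.asarray(volume)
    if vol.ndim == 3:
        vol = vol[None]
    if vol.ndim != 4:
        raise ValueError("expected slice x coil x kx x ky")
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=vol.astype(np.complex64))
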