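"""The multi-coil SENSE measurement operator A = P F S.

``S`` multiplies the image by each coil's complex sensitivity profile, ``F``
is the centered orthonormal 2D Fourier transform applied per coil, and ``P``
masks out unsampled phase-encode lines.  With normalized maps (per-pixel
root-sum-of-squares of 1) and full sampling, ``A`` is an isometry, so
``A^H A = I`` — the contract every downstream solver and loss relies on.

The normal-equation solver is plain conjugate gradients on
``(A^H A + lam I) x = rhs``; it is matrix-free and Hermitian-PSD by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from ._fft import fft2c, ifft2c
from .synth import CoilMaps

__all__ = [
    "SamplingMask",
    "MultiCoilKSpace",
    "SenseOperator",
    "fft2c",
    "ifft2c",
    "make_mask",
    "apply_forward",
    "apply_adjoint",
    "solve_normal",
    "pseudo_inverse",
    "read_kspace_h5",
    "CgWarning",
]


class CgWarning(UserWarning):
    """Raised (as a warning) when conjugate gradients exhausts maxiter."""


@dataclass(frozen=True)
class SamplingMask:
    """Phase-encode undersampling pattern (constant along frequency encode).

    ``pattern`` is boolean (Nx, Ny): True lines are acquired.  The central
    ``acs_width`` phase-encode lines are always fully sampled.
    """

    pattern: np.ndarray
    acs_width: int
    acceleration: float

    def __post_init__(self) -> None:
        if self.pattern.dtype != bool or self.pattern.ndim != 2:
            raise ValueError("mask pattern must be a boolean 2D array")

    @property
    def lines(self) -> np.ndarray:
        """Boolean vector over phase-encode (ky) lines."""
        return self.pattern[0]


@dataclass
class MultiCoilKSpace:
    """K-space samples of one slice: ``data`` is (Nc, Nx, Ny) complex.

    ``noise_sigma`` holds either the scalar complex noise variance per coil
    sample (post-whitening) or the full Nc x Nc coil covariance
    (pre-whitening).  ``mask`` is None for fully sampled data.
    """

    data: np.ndarray
    mask: SamplingMask | None = None
    noise_sigma: float | np.ndarray | None = None

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]


def make_mask(shape: tuple[int, int], R: float, acs_width: int,
              seed: int) -> SamplingMask:
    """Uniform-random phase-encode line selection with a fully kept ACS block.

    The total sampled fraction is 1/R counted over all lines including the
    ACS region; the number of sampled lines is ``floor(Ny / R)``.
    """
    nx, ny = shape
    if acs_width >= ny:
        raise ValueError("acs_width must be smaller than the phase-encode size")
    if R < 1:
        raise ValueError("acceleration R must be >= 1")
    n_lines = int(ny // R)
    if n_lines < acs_width:
        raise ValueError(
            f"infeasible mask: 1/R fraction gives {n_lines} lines but the ACS "
            f"region alone needs {acs_width}")
    lines = np.zeros(ny, dtype=bool)
    lo = ny // 2 - acs_width // 2
    lines[lo:lo + acs_width] = True
    remaining = np.flatnonzero(~lines)
    rng = np.random.default_rng(seed)
    extra = rng.choice(remaining, size=n_lines - acs_width, replace=False)
    lines[extra] = True
    pattern = np.broadcast_to(lines, (nx, ny)).copy()
    return SamplingMask(pattern=pattern, acs_width=acs_width, acceleration=R)


@dataclass
class SenseOperator:
    """A = P F S with a centered orthonormal FFT convention.

    ``mask=None`` means full sampling (P = I).
    """

    maps: CoilMaps
    mask: SamplingMask | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.maps.shape[-2:]

    def forward(self, image: np.ndarray) -> MultiCoilKSpace:
        return apply_forward(self, image)

    def adjoint(self, y: MultiCoilKSpace) -> np.ndarray:
        return apply_adjoint(self, y)

    def normal(self, image: np.ndarray) -> np.ndarray:
        """A^H A x without materialising the intermediate container."""
        ks = fft2c(self.maps.maps * image)
        if self.mask is not None:
            ks = ks * self.mask.pattern
        return np.sum(np.conj(self.maps.maps) * ifft2c(ks), axis=0)


def apply_forward(op: SenseOperator, image: np.ndarray) -> MultiCoilKSpace:
    """y = P F S x."""
    if image.shape != op.shape:
        raise ValueError(f"image shape {image.shape} != operator grid {op.shape}")
    ks = fft2c(op.maps.maps * image)
    if op.mask is not None:
        ks = ks * op.mask.pattern
    return MultiCoilKSpace(data=ks, mask=op.mask)


def apply_adjoint(op: SenseOperator, y: MultiCoilKSpace) -> np.ndarray:
    """A^H y = S^H F^{-1} P^T y (coil-combined image)."""
    data = y.data if isinstance(y, MultiCoilKSpace) else y
    if data.shape[-2:] != op.shape:
        raise ValueError(f"k-space shape {data.shape} incompatible with grid {op.shape}")
    if op.mask is not None:
        data = data * op.mask.pattern
    return np.sum(np.conj(op.maps.maps) * ifft2c(data), axis=0)


def solve_normal(op: SenseOperator, rhs: np.ndarray, lam: float = 0.0,
                 tol: float = 1e-8, maxiter: int = 500) -> np.ndarray:
    """Solve (A^H A + lam I) x = rhs by conjugate gradients.

    Emits a :class:`CgWarning` if the relative residual has not reached
    ``tol`` within ``maxiter`` iterations; the best iterate is still
    returned.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    rhs_norm = np.linalg.norm(rhs)
    if rhs_norm == 0:
        return np.zeros_like(rhs)

    def mv(x: np.ndarray) -> np.ndarray:
        return op.normal(x) + lam * x

    x = np.zeros_like(rhs)
    r = rhs.copy()
    p = r.copy()
    rs = np.real(np.vdot(r, r))
    for _ in range(maxiter):
        if np.sqrt(rs) / rhs_norm <= tol:
            return x
        ap = mv(p)
        alpha = rs / np.real(np.vdot(p, ap))
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = np.real(np.vdot(r, r))
        p = r + (rs_new / rs) * p
        rs = rs_new
    if np.sqrt(rs) / rhs_norm > tol:
        warnings.warn(
            f"CG did not reach tol={tol:g} in {maxiter} iterations "
            f"(residual {np.sqrt(rs) / rhs_norm:.2e})", CgWarning)
    return x


def pseudo_inverse(op: SenseOperator, y: MultiCoilKSpace,
                   tol: float = 1e-8, maxiter: int = 500) -> np.ndarray:
    """A^+ y, computed as the minimum-norm normal-equation solution."""
    return solve_normal(op, apply_adjoint(op, y), lam=0.0, tol=tol,
                        maxiter=maxiter)


def read_kspace_h5(path) -> np.ndarray:
    """Read a fastMRI-dialect k-space file: dataset 'kspace', slice x coil x kx x ky."""
    with h5py.File(path, "r") as f:
        return np.asarray(f["kspace"])


def save_mask(path, mask: SamplingMask) -> None:
    """Export the boolean sampling pattern as an NPY array."""
    np.save(path, mask.pattern)


def load_mask(path, acs_width: int = 0,
              acceleration: float = float("nan")) -> SamplingMask:
    """Import a boolean pattern written by :func:`save_mask`."""
    pattern = np.load(path)
    return SamplingMask(pattern=np.asarray(pattern, dtype=bool),
                        acs_width=acs_width, acceleration=acceleration)
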