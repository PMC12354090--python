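"""Centered orthonormal FFT helpers shared by the simulator and the operator."""

from __future__ import annotations

import numpy as np


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


def ifft2c(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(y, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))
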