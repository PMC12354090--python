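"""Independent dense-matrix oracles used by the operator and solver tests.

The dense SENSE matrix is assembled from first principles — an explicit
centered orthonormal DFT matrix, diagonal sensitivity blocks and mask rows —
without calling the package's matrix-free operator, so agreement between the
two is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def centered_dft_matrix(n: int) -> np.ndarray:
    """Entry (k, l) = exp(-2 pi i (k - c)(l - c) / n) / sqrt(n), c = n // 2."""
    c = n // 2
    k = np.arange(n) - c
    return np.exp(-2j * np.pi * np.outer(k, k) / n) / np.sqrt(n)


def dense_sense_matrix(maps: np.ndarray,
                       mask_pattern: np.ndarray | None) -> np.ndarray:
    """Dense (Nc*N, N) matrix of A = P F S for row-major flattened images."""
    nc, nx, ny = maps.shape
    f2 = np.kron(centered_dft_matrix(nx), centered_dft_matrix(ny))
    blocks = []
    for c in range(nc):
        block = f2 * maps[c].ravel()[None, :]  # F2 @ diag(S_c)
        if mask_pattern is not None:
            block = block * mask_pattern.ravel()[:, None]
        blocks.append(block)
    return np.vstack(blocks)


def dense_normal_solve(a_dense: np.ndarray, rhs: np.ndarray,
                       lam: float) -> np.ndarray:
    """(A^H A + lam I)^{-1} rhs on flattened vectors."""
    n = a_dense.shape[1]
    m = a_dense.conj().T @ a_dense + lam * np.eye(n)
    return np.linalg.solve(m, rhs.ravel())
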