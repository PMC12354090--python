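"""Unrolled model-based reconstruction (MoDL).

The network alternates a conjugate-gradient data-consistency solve

    dc(z) = argmin_x ||y - A x||^2 + lam ||x - z||^2
          = (A^H A + lam I)^{-1} (A^H y + lam z)

with a small shared convolutional denoiser D applied after each solve,
starting from the adjoint image A^H y.  The whole unroll is trained
end-to-end with the normalized RMSE objective ||x_ref - x_hat|| / ||x_ref||.

Gradients through the DC block use the implicit-function form: the solve is
linear in z for fixed lam, so the adjoint of the block is lam (A^H A +
lam I)^{-1}, evaluated with one extra CG solve.  lam is a single scalar,
parameterized as exp(log_lam) to stay positive and trainable by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._nn import Adam, Residual, init_conv_net
from .forward_model import (MultiCoilKSpace, SenseOperator, apply_adjoint,
                            solve_normal)
from .gsure import c2r, r2c, real_dot

__all__ = [
    "ModlNetwork",
    "ModlTrainConfig",
    "dc_block",
    "modl_forward",
    "nrmse_loss",
    "train_modl",
]


def dc_block(z: np.ndarray, y: MultiCoilKSpace, op: SenseOperator,
             lam: float, tol: float = 1e-6, maxiter: int = 500) -> np.ndarray:
    """Regularized data-consistency solve toward the measurements."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    rhs = apply_adjoint(op, y) + lam * z
    return solve_normal(op, rhs, lam=lam, tol=tol, maxiter=maxiter)


def nrmse_loss(x_hat: np.ndarray, x_ref: np.ndarray) -> float:
    """||x_ref - x_hat||_2 / ||x_ref||_2 on the complex vectors."""
    if x_hat.shape != x_ref.shape:
        raise ValueError("shape mismatch")
    ref_norm = np.linalg.norm(x_ref)
    if ref_norm == 0:
        raise ValueError("reference image is zero")
    return float(np.linalg.norm(x_ref - x_hat) / ref_norm)


class ModlNetwork:
    """Shared-denoiser unrolled network H_theta(y, A)."""

    def __init__(self, shape: tuple[int, int], *, n_unrolls: int = 6,
                 hidden: int = 24, n_hidden: int = 2, lam_init: float = 1.0,
                 train_lam: bool = True, cg_tol: float = 1e-6,
                 cg_maxiter: int = 50, seed: int = 0) -> None:
        if n_unrolls < 1:
            raise ValueError("n_unrolls must be >= 1")
        self.shape = shape
        self.n_unrolls = n_unrolls
        self.cg_tol = cg_tol
        self.cg_maxiter = cg_maxiter
        self.train_lam = train_lam
        rng = np.random.default_rng(seed)
        self.denoiser = Residual(init_conv_net(2, 2, hidden, n_hidden, rng,
                                               zero_last=True))
        self.log_lam = np.array([np.log(lam_init)])

    @property
    def lam(self) -> float:
        return float(np.exp(self.log_lam[0]))

    @property
    def params(self) -> list[np.ndarray]:
        ps = list(self.denoiser.params)
        if self.train_lam:
            ps.append(self.log_lam)
        return ps

    def forward(self, y: MultiCoilKSpace, op: SenseOperator,
                with_cache: bool = False):
        lam = self.lam
        x = apply_adjoint(op, y)
        caches = []
        for _ in range(self.n_unrolls):
            z = x
            xdc = dc_block(z, y, op, lam, tol=self.cg_tol,
                           maxiter=self.cg_maxiter)
            out, cache = self.denoiser.forward(c2r(xdc)[None])
            x = r2c(out[0])
            caches.append((z, xdc, cache))
        if with_cache:
            return x, caches
        return x

    def backward(self, caches, op: SenseOperator,
                 gx: np.ndarray) -> list[np.ndarray]:
        """Gradients of <gx, output> w.r.t. parameters (real-composite)."""
        lam = self.lam
        net_grads = [np.zeros_like(p) for p in self.denoiser.params]
        glam = 0.0
        for z, xdc, cache in reversed(caches):
            gdc_r, grads = self.denoiser.backward(cache, c2r(gx)[None])
            for acc, g in zip(net_grads, grads):
                acc += g
            gdc = r2c(gdc_r[0])
            # adjoint of the DC solve: lam * (A^H A + lam I)^{-1}
            minv_gdc = solve_normal(op, gdc, lam=lam, tol=self.cg_tol,
                                    maxiter=self.cg_maxiter)
            gx = lam * minv_gdc
            glam += real_dot(minv_gdc, z - xdc)
        if self.train_lam:
            return net_grads + [np.array([glam * lam])]
        return net_grads


def modl_forward(net: ModlNetwork, y: MultiCoilKSpace,
                 op: SenseOperator) -> np.ndarray:
    """Run the unrolled reconstruction; deterministic given fixed weights."""
    return net.forward(y, op)


@dataclass
class ModlTrainConfig:
    n_unrolls: int = 6
    epochs: int = 3
    lr: float = 1e-3
    hidden: int = 24
    n_hidden: int = 2
    lam_init: float = 1.0
    train_lam: bool = True
    cg_tol: float = 1e-6
    cg_maxiter: int = 50
    seed: int = 0
    verbose: bool = False


def train_modl(pairs: Sequence[tuple[MultiCoilKSpace, SenseOperator, np.ndarray]],
               config: ModlTrainConfig | None = None) -> ModlNetwork:
    """End-to-end training with the NRMSE objective, batch size 1."""
    if config is None:
        config = ModlTrainConfig()
    if not pairs:
        raise ValueError("pairs must be non-empty")
    shape = pairs[0][2].shape
    net = ModlNetwork(shape, n_unrolls=config.n_unrolls, hidden=config.hidden,
                      n_hidden=config.n_hidden, lam_init=config.lam_init,
                      train_lam=config.train_lam, cg_tol=config.cg_tol,
                      cg_maxiter=config.cg_maxiter, seed=config.seed)
    opt = Adam(net.params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        epoch_loss = 0.0
        for i in order:
            y, op, target = pairs[i]
            x_hat, caches = net.forward(y, op, with_cache=True)
            err = x_hat - target
            err_norm = np.linalg.norm(err)
            ref_norm = np.linalg.norm(target)
            loss = float(err_norm / ref_norm)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"MoDL loss diverged (epoch {epoch}): {loss}")
            if err_norm > 0:
                gx = err / (err_norm * ref_norm)
                grads = net.backward(caches, op, gx)
                opt.step(grads)
            epoch_loss += loss
        history.append(epoch_loss / len(pairs))
        if config.verbose:
            print(f"[modl] epoch {epoch + 1}/{config.epochs} "
                  f"loss {history[-1]:.4f}")
    net.history = history
    return net
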