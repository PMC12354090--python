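import numpy as np
import pytest

from _oracles import dense_normal_solve, dense_sense_matrix
from conftest import random_complex
from gsuremri.forward_model import (MultiCoilKSpace, SenseOperator,
                                    apply_adjoint, apply_forward, make_mask)
from gsuremri.modl import (ModlNetwork, ModlTrainConfig, dc_block,
                           modl_forward, nrmse_loss, train_modl)
from gsuremri.synth import make_coil_maps, make_phantom


def _masked_op(shape=(8, 8), n_coils=2, R=2, seed=0):
    maps = make_coil_maps(shape, n_coils, seed=seed, normalize=True)
    mask = make_mask(shape, R, 2, seed + 1)
    return SenseOperator(maps=maps, mask=mask)


class TestNrmse:
    def test_reference_values(self):
        rng = np.random.default_rng(0)
        x = random_complex(rng, (8, 8))
        assert nrmse_loss(x, x) == 0.0
        assert np.isclose(nrmse_loss(np.zeros_like(x), x), 1.0)
        assert np.isclose(nrmse_loss(2 * x, x), 1.0)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            nrmse_loss(np.ones((4, 4)), np.zeros((4, 4)))


class TestDcBlock:
    @pytest.mark.parametrize("lam", [0.01, 1.0, 100.0])
    def test_matches_dense_closed_form(self, lam):
        op = _masked_op()
        a = dense_sense_matrix(op.maps.maps, op.mask.pattern)
        rng = np.random.default_rng(1)
        x = random_complex(rng, (8, 8))
        y = apply_forward(op, x)
        z = random_complex(rng, (8, 8))
        out = dc_block(z, y, op, lam, tol=1e-12, maxiter=3000)
        rhs = apply_adjoint(op, y) + lam * z
        dense = dense_normal_solve(a, rhs, lam).reshape((8, 8))
        assert np.linalg.norm(out - dense) / np.linalg.norm(dense) <= 1e-6

    def test_large_lambda_returns_z(self):
        op = _masked_op()
        rng = np.random.default_rng(2)
        z = random_complex(rng, (8, 8))
        y = apply_forward(op, random_complex(rng, (8, 8)))
        out = dc_block(z, y, op, lam=1e8, tol=1e-12)
        assert np.linalg.norm(out - z) / np.linalg.norm(z) <= 1e-5

    def test_small_lambda_full_sampling_returns_adjoint(self):
        maps = make_coil_maps((8, 8), 2, seed=3)
        op = SenseOperator(maps=maps)
        rng = np.random.default_rng(3)
        x = random_complex(rng, (8, 8))
        y = apply_forward(op, x)
        out = dc_block(np.zeros_like(x), y, op, lam=1e-10, tol=1e-12)
        assert np.allclose(out, apply_adjoint(op, y), atol=1e-6)

    def test_nonpositive_lambda_raises(self):
        op = _masked_op()
        y = apply_forward(op, np.ones((8, 8), dtype=complex))
        with pytest.raises(ValueError):
            dc_block(np.zeros((8, 8), dtype=complex), y, op, lam=0.0)


class TestModlForward:
    def test_identity_denoiser_full_sampling_tiny_lambda(self):
        maps = make_coil_maps((8, 8), 2, seed=4)
        op = SenseOperator(maps=maps)
        rng = np.random.default_rng(4)
        x = random_complex(rng, (8, 8))
        y = apply_forward(op, x)
        net = ModlNetwork((8, 8), n_unrolls=1, lam_init=1e-8, hidden=4, seed=0)
        out = modl_forward(net, y, op)  # zero-init residual net = identity
        assert np.linalg.norm(out - apply_adjoint(op, y)) <= 1e-5

    def test_identity_denoiser_converges_to_regularized_fixed_point(self):
        """With D = I the unrolls iterate x -> (A^H A + lam)^{-1}(A^H y + lam x),
        whose fixed point is the lam-regularized least-squares solution of the
        doubled problem; compare against its dense evaluation."""
        op = _masked_op(seed=6)
        a = dense_sense_matrix(op.maps.maps, op.mask.pattern)
        rng = np.random.default_rng(5)
        x = random_complex(rng, (8, 8))
        y = apply_forward(op, x)
        lam = 0.5
        net = ModlNetwork((8, 8), n_unrolls=40, lam_init=lam, hidden=4,
                          cg_tol=1e-12, cg_maxiter=3000, seed=0)
        out = modl_forward(net, y, op)
        # iterate the dense map from the same starting point A^H y; the two
        # sequences must agree step for step up to CG accuracy
        rhs = apply_adjoint(op, y).ravel()
        n = 64
        m = a.conj().T @ a + lam * np.eye(n)
        xk = rhs.copy()
        for _ in range(40):
            xk = np.linalg.solve(m, rhs + lam * xk)
        assert np.linalg.norm(out.ravel() - xk) / np.linalg.norm(xk) <= 1e-5

    def test_forward_is_deterministic(self):
        op = _masked_op(seed=7)
        y = apply_forward(op, np.ones((8, 8), dtype=complex))
        net = ModlNetwork((8, 8), n_unrolls=2, hidden=4, seed=1)
        assert np.array_equal(modl_forward(net, y, op),
                              modl_forward(net, y, op))

    def test_default_unroll_count(self):
        assert ModlNetwork((8, 8)).n_unrolls == 6


class TestTraining:
    def _pairs(self, n=5, shape=(12, 12), seed=0):
        pairs = []
        for i in range(n):
            ph = make_phantom((16, 16), 3, seed + i)
            truth = ph.image[2:14, 2:14]
            maps = make_coil_maps(shape, 2, seed=seed + 50 + i)
            mask = make_mask(shape, 2, 4, seed + 100 + i)
            op = SenseOperator(maps=maps, mask=mask)
            y = apply_forward(op, truth)
            pairs.append((y, op, truth))
        return pairs

    def test_overfit_small_set(self):
        pairs = self._pairs()
        cfg = ModlTrainConfig(n_unrolls=6, epochs=100, lr=5e-3, hidden=12,
                              seed=0)
        net = train_modl(pairs, cfg)
        final = np.mean([nrmse_loss(modl_forward(net, y, op), t)
                         for y, op, t in pairs])
        assert final < 0.05
        assert net.history[-1] < net.history[0]

    def test_training_is_deterministic(self):
        pairs = self._pairs(n=2)
        cfg = ModlTrainConfig(n_unrolls=2, epochs=2, hidden=4, seed=5)
        n1 = train_modl(pairs, cfg)
        n2 = train_modl(pairs, cfg)
        for p1, p2 in zip(n1.params, n2.params):
            assert np.array_equal(p1, p2)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """End-to-end unrolled gradient vs central differences, incl. lam."""
        shape = (8, 8)
        op = _masked_op(seed=8)
        rng = np.random.default_rng(9)
        truth = random_complex(rng, shape)
        y = apply_forward(op, truth)
        net = ModlNetwork(shape, n_unrolls=2, hidden=3, n_hidden=1,
                          cg_tol=1e-12, cg_maxiter=2000, seed=2)
        # make the denoiser non-trivial so gradients flow everywhere
        for p in net.denoiser.params:
            p += 0.05 * rng.standard_normal(p.shape)

        def loss():
            return nrmse_loss(net.forward(y, op), truth)

        x_hat, caches = net.forward(y, op, with_cache=True)
        err = x_hat - truth
        gx = err / (np.linalg.norm(err) * np.linalg.norm(truth))
        grads = net.backward(caches, op, gx)
        eps = 1e-6
        for pi, (p, g) in enumerate(zip(net.params, grads)):
            flat = p.reshape(-1)
            idxs = rng.choice(flat.size, size=min(5, flat.size), replace=False)
            for j in idxs:
                orig = flat[j]
                flat[j] = orig + eps
                lp = loss()
                flat[j] = orig - eps
                lm = loss()
                flat[j] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g.reshape(-1)[j]) <= 1e-5, \
                    f"param {pi} coord {j}"
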