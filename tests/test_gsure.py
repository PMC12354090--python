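"""Unit and oracle tests for the GSURE denoising stage.

The key scientific checks: the Monte-Carlo divergence is unbiased for linear
maps (exact trace oracle), the GSURE loss matches the supervised loss in
expectation up to the ||x||^2 constant, and self-supervised training of an
explicit linear denoiser recovers the closed-form Wiener filter.
"""

import numpy as np
import pytest

from gsuremri.forward_model import MultiCoilKSpace, SenseOperator, apply_adjoint
from gsuremri.gsure import (DenoiserModel, GsureSample, GsureTrainConfig,
                            denoise_dataset, gsure_loss, make_gsure_sample,
                            mc_divergence, supervised_loss, train_denoiser)
from gsuremri.synth import make_coil_maps, make_phantom


def _gaussian_samples(shape, n, sigma_sq, tau_sq=1.0, seed=0):
    """Single-coil identity-map problems: u = (x + n) / sigma_r^2."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        x = np.sqrt(tau_sq / 2) * (rng.standard_normal(shape)
                                   + 1j * rng.standard_normal(shape))
        noise = np.sqrt(sigma_sq / 2) * (rng.standard_normal(shape)
                                         + 1j * rng.standard_normal(shape))
        adj = x + noise
        out.append((GsureSample(u=adj / (sigma_sq / 2), pinv=adj,
                                sigma_sq=sigma_sq), x))
    return out


class TestMcDivergence:
    def test_identity_map_gives_real_dimension(self):
        x = np.zeros((16, 16), dtype=complex)
        rng = np.random.default_rng(0)
        est = np.mean([mc_divergence(lambda v: v, x, rng=rng)
                       for _ in range(100)])
        assert abs(est - 512) / 512 <= 0.02

    def test_zero_map_is_exactly_zero(self):
        x = np.ones((8, 8), dtype=complex)
        assert mc_divergence(lambda v: np.zeros_like(v), x, probe_seed=0) == 0.0

    def test_linear_map_matches_trace(self):
        # off-diagonal scale keeps the 500-probe Hutchinson variance well
        # below the 2% band around the trace
        rng = np.random.default_rng(1)
        model = DenoiserModel((8, 8), mode="linear")
        model.params[0][:] = 0.5 * np.eye(128) + \
            0.02 * rng.standard_normal((128, 128)) / np.sqrt(128)
        g = model.as_callable()
        x = (rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8)))
        est = np.mean([mc_divergence(g, x, rng=rng) for _ in range(500)])
        exact = model.exact_divergence()
        assert abs(est - exact) / abs(exact) <= 0.02

    def test_eps_invariance_for_linear_maps(self):
        model = DenoiserModel((8, 8), mode="linear")
        x = np.ones((8, 8), dtype=complex)
        vals = [mc_divergence(model.as_callable(), x, eps=e, probe_seed=7)
                for e in (1e-2, 1e-3, 1e-4)]
        assert np.allclose(vals, vals[0], rtol=1e-6)


class TestGsureLoss:
    def test_zero_map_gives_zero(self):
        (s, _), = _gaussian_samples((8, 8), 1, 0.1)
        assert gsure_loss(lambda v: np.zeros_like(v), s, probe_seed=0) == 0.0

    def test_constant_map_closed_form(self):
        (s, _), = _gaussian_samples((8, 8), 1, 0.1, seed=2)
        c = np.full((8, 8), 0.3 + 0.2j)
        val = gsure_loss(lambda v: c, s, probe_seed=0)
        expected = np.sum(np.abs(c) ** 2) - 2 * np.sum(
            c.real * s.pinv.real + c.imag * s.pinv.imag)
        assert np.isclose(val, expected)

    def test_unbiasedness_for_linear_denoiser(self):
        """E[GSURE] = E[||g(u) - x||^2] - ||x||^2 over the noise distribution."""
        rng = np.random.default_rng(3)
        shape = (8, 8)
        model = DenoiserModel(shape, mode="linear")
        model.params[0][:] = 0.6 * np.eye(128) + \
            0.05 * rng.standard_normal((128, 128)) / np.sqrt(128)
        g = model.as_callable()
        ph = make_phantom((16, 16), 2, 0)
        x = ph.image[4:12, 4:12]
        sigma_sq = 0.2
        gs_vals, sup_vals = [], []
        for _ in range(2000):
            noise = np.sqrt(sigma_sq / 2) * (rng.standard_normal(shape)
                                             + 1j * rng.standard_normal(shape))
            adj = x + noise
            s = GsureSample(u=adj / (sigma_sq / 2), pinv=adj, sigma_sq=sigma_sq)
            gs_vals.append(gsure_loss(g, s, rng=rng))
            sup_vals.append(np.sum(np.abs(g(s.u) - x) ** 2)
                            - np.sum(np.abs(x) ** 2))
        gap = abs(np.mean(gs_vals) - np.mean(sup_vals))
        assert gap / abs(np.mean(sup_vals)) <= 0.02

    def test_loss_interface_has_no_truth_argument(self):
        import inspect
        assert "truth" not in inspect.signature(gsure_loss).parameters


class TestSupervisedLoss:
    def test_exact_reproduction_gives_zero(self):
        (s, x), = _gaussian_samples((8, 8), 1, 0.1, seed=4)
        assert supervised_loss(lambda v: x, s, x) == 0.0

    def test_zero_map_gives_half_energy(self):
        (s, x), = _gaussian_samples((8, 8), 1, 0.1, seed=5)
        val = supervised_loss(lambda v: np.zeros_like(v), s, x)
        assert np.isclose(val, 0.5 * np.sum(np.abs(x) ** 2))


class TestTraining:
    def test_linear_mode_learns_wiener_filter(self):
        """GSURE-trained linear denoiser approaches the closed-form MMSE map.

        For x ~ CN(0, tau^2 I) and white noise of complex variance sigma^2,
        the optimal map on u is W* = (sigma_r^2 tau^2 / (tau^2 + sigma^2)) I.
        The filter is diagonal for isotropic signal and noise, so the map is
        parameterized diagonally (an unconstrained 128 x 128 matrix would
        need far more samples than any training run to pin down every
        off-diagonal to the same tolerance).
        """
        tau_sq, sigma_sq = 1.0, 0.5
        data = [s for s, _ in _gaussian_samples((8, 8), 4000, sigma_sq,
                                                tau_sq, seed=6)]
        cfg = GsureTrainConfig(mode="linear", linear_structure="diagonal",
                               epochs=30, lr=3e-3, batch_size=16, seed=0,
                               standardize=False)
        model = train_denoiser(data, cfg)
        w_star = (sigma_sq / 2) * tau_sq / (tau_sq + sigma_sq)
        err = np.max(np.abs(model.params[0] - w_star)) / w_star
        assert err <= 0.05

    def test_network_training_is_deterministic(self):
        data = [s for s, _ in _gaussian_samples((8, 8), 8, 0.2, seed=7)]
        cfg = GsureTrainConfig(epochs=2, hidden=4, seed=3)
        m1 = train_denoiser(data, cfg)
        m2 = train_denoiser(data, cfg)
        for p1, p2 in zip(m1.params, m2.params):
            assert np.array_equal(p1, p2)

    def test_denoise_dataset_preserves_order_and_count(self):
        pairs = _gaussian_samples((8, 8), 5, 0.2, seed=8)
        data = [s for s, _ in pairs]
        model = DenoiserModel((8, 8), mode="network", hidden=4, seed=0)
        out = denoise_dataset(model, data)
        assert len(out) == 5
        # zero-initialised residual net acts as the identity on its input
        gain = model.gain(data[0].sigma_r_sq)
        assert np.allclose(out[0], data[0].u * gain)


class TestSampleConstruction:
    def test_full_sampling_pinv_equals_adjoint(self, phantom16, maps16):
        from gsuremri.synth import NoiseSpec, simulate_kspace
        ks = simulate_kspace(phantom16, maps16,
                             NoiseSpec(coil_covariance=0.01 * np.eye(4), seed=0))
        ks = MultiCoilKSpace(data=ks.data, noise_sigma=0.01)
        op = SenseOperator(maps=maps16)
        s = make_gsure_sample(ks, op)
        adj = apply_adjoint(op, ks)
        assert np.allclose(s.pinv, adj)
        assert np.allclose(s.u, adj / 0.005)
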