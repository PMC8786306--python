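"""VDAM optimizer: elementary updates, moment recursions, schedule
arithmetic, class substitution and degenerate-configuration behaviour."""

import numpy as np
import pytest

from cryoclass.em import em_update
from cryoclass.grids import fourier_grid
from cryoclass.likelihood import SignalPrior, SufficientStats
from cryoclass.simulate import make_classes, simulate_particles
from cryoclass.vdam import (MomentState, VdamConfig, batch_schedule,
                            init_gaussian_blobs, rescaled_gradient, run_vdam,
                            substitute_inactive_class, update_moments,
                            vdam_update, vmgd_update)


def _random_stats(K=1, box=8, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    g = fourier_grid(box)
    cx = box // 2 + 1
    b = (rng.standard_normal((K, box, cx))
         + 1j * rng.standard_normal((K, box, cx))) * scale
    f = (rng.random((K, box, cx)) + 0.5) * scale
    b[:, ~g.active_half] = 0
    f[:, ~g.active_half] = 0
    return SufficientStats(b=b, f=f, mass=np.full(K, 1.0 / K),
                           n_particles=4.0), g


class TestElementaryUpdates:
    def test_rescaled_gradient_batch_size_invariance(self):
        # duplicating every particle doubles G and F; Ghat is unchanged
        stats, g = _random_stats()
        rng = np.random.default_rng(1)
        v = rng.standard_normal(stats.b.shape) + 0j
        grad = stats.f * v - stats.b
        eps1 = 1e-12 * stats.f[:, g.active_half].mean()
        g1 = rescaled_gradient(grad, stats.f, eps1)
        g2 = rescaled_gradient(2 * grad, 2 * stats.f, eps1)
        m = g.active_half
        assert np.abs((g1 - g2)[:, m]).max() < 1e-10 * np.abs(g1[:, m]).max()

    def test_rescaled_gradient_limits(self):
        stats, g = _random_stats()
        assert np.all(rescaled_gradient(np.zeros_like(stats.b), stats.f,
                                        1e-8) == 0)
        gr = np.ones_like(stats.b)
        np.testing.assert_allclose(
            rescaled_gradient(gr, np.zeros_like(stats.f), 0.5), gr / 0.5)

    def test_vmgd_full_batch_unit_rate_equals_em(self):
        stats, g = _random_stats()
        tau = SignalPrior(np.full(g.n_shells, 2.0))
        inv_tau2 = np.where(g.active_half, tau.inv()[g.shell_half], 0.0)
        rng = np.random.default_rng(2)
        v = (rng.standard_normal(stats.b.shape)
             + 1j * rng.standard_normal(stats.b.shape))
        v[:, ~g.active_half] = 0
        grad = stats.f * v - stats.b
        out = vmgd_update(v, grad, stats.f, inv_tau2, eta=1.0)
        expected = em_update(stats, tau)
        m = g.active_half
        assert np.abs((out - expected)[:, m]).max() < 1e-10

    def test_vmgd_zero_rate_is_identity(self):
        stats, g = _random_stats()
        v = np.ones_like(stats.b)
        out = vmgd_update(v, stats.b.copy(), stats.f, 0.0, eta=0.0)
        np.testing.assert_array_equal(out, v)

    def test_vmgd_noop_at_em_fixed_point(self):
        stats, g = _random_stats()
        tau = SignalPrior(np.full(g.n_shells, 2.0))
        inv_tau2 = np.where(g.active_half, tau.inv()[g.shell_half], 0.0)
        v_star = em_update(stats, tau)
        grad = stats.f * v_star - stats.b
        for eta in (0.1, 0.5, 1.0):
            out = vmgd_update(v_star, grad, stats.f, inv_tau2, eta)
            assert np.abs(out - v_star).max() < 1e-12


class TestMoments:
    def test_beta1_zero_copies_current_gradient(self):
        state = MomentState.zeros(1, 8)
        g1 = np.full((1, 8, 5), 1 + 2j)
        g2 = np.full((1, 8, 5), 3 - 1j)
        new = update_moments(state, g1, g2, beta1=0.0, beta2=0.5)
        np.testing.assert_array_equal(new.m1, g1)
        np.testing.assert_array_equal(new.m2, g2)

    def test_constant_gradient_closed_form(self):
        # m(n) = (1 - beta1^n) g for constant gradient from m(0) = 0
        state = MomentState.zeros(1, 8)
        gconst = np.full((1, 8, 5), 0.7 - 0.2j)
        beta1 = 0.9
        for n in range(1, 12):
            state = update_moments(state, gconst, gconst, beta1=beta1)
            expected = (1 - beta1 ** n) * gconst
            np.testing.assert_allclose(state.m1, expected, rtol=1e-12)
            np.testing.assert_allclose(state.m2, expected, rtol=1e-12)

    def test_identical_halves_decay_second_moment(self):
        state = MomentState.zeros(1, 8)
        state.u[:] = 1.0
        gsame = np.ones((1, 8, 5), complex)
        beta2 = 0.999
        for n in range(1, 5):
            state = update_moments(state, gsame, gsame, beta2=beta2)
            np.testing.assert_allclose(state.u, beta2 ** n, rtol=1e-12)

    def test_constant_gradient_u_closed_form(self):
        state = MomentState.zeros(1, 8)
        g1 = np.full((1, 8, 5), 1.0 + 0j)
        g2 = np.full((1, 8, 5), 0.0 + 0j)
        beta2 = 0.999
        for n in range(1, 8):
            state = update_moments(state, g1, g2, beta2=beta2)
            np.testing.assert_allclose(state.u, 1 - beta2 ** n, rtol=1e-12)


class TestVdamUpdate:
    def test_zero_fsc_is_pure_shrinkage(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((8, 5)) + 0j
        out = vdam_update(v, np.ones_like(v), np.ones((8, 5)),
                          np.zeros(4), eta=0.3, eps2=1e-8)
        np.testing.assert_allclose(out, 0.7 * v, rtol=1e-12)

    def test_unit_fsc_vanishing_u_step(self):
        v = np.zeros((8, 5), complex)
        m = np.full((8, 5), 0.5 + 0j)
        # uncapped branch: step = -eta m / eps2 while eta/eps2 <= 1
        out = vdam_update(v, m, np.zeros((8, 5)), np.ones(4),
                          eta=0.1, eps2=0.25)
        np.testing.assert_allclose(out, -0.1 * m / 0.25, rtol=1e-12)
        # the multiplier saturates at 1 (never beyond the EM displacement)
        out2 = vdam_update(v, m, np.zeros((8, 5)), np.ones(4),
                           eta=1.0, eps2=0.25)
        np.testing.assert_allclose(out2, -m, rtol=1e-12)

    def test_two_by_two_hand_evaluation(self):
        # tiny grid, every quantity written out by hand
        box = 4
        g = fourier_grid(box)
        v = np.arange(box * (box // 2 + 1)).reshape(box, 3) + 0j
        m = np.full((box, 3), 2.0 + 0j)
        u = np.full((box, 3), 4.0)
        curve = np.array([1.0, 0.5])
        eta, eps2 = 0.5, 1.0
        out = vdam_update(v, m, u, curve, eta, eps2)
        c = np.clip(curve, 0, 1)[g.shell_half]
        expected = v - eta * (c * m / 3.0 + (1 - c) * v)
        np.testing.assert_allclose(out, expected, rtol=1e-12)


class TestBatchSchedule:
    @pytest.mark.parametrize("n,mode,stage,size,eta", [
        (4_000_000, "2d", "initial", 10000, 0.9),
        (10_000, "2d", "initial", 200, 0.9),
        (100_000, "2d", "later", 5000, 0.3),
        (4_000_000, "3d", "initial", 5000, 0.9),
        (100_000, "3d", "later", 10000, 0.5),
        (10_000_000, "2d", "later", 100000, 0.3),
        (10_000_000, "3d", "later", 50000, 0.5),
        (5_000, "2d", "later", 1000, 0.3),
    ])
    def test_printed_clamps(self, n, mode, stage, size, eta):
        assert batch_schedule(n, mode, stage) == (size, eta)

    def test_capped_at_dataset_size(self):
        size, _ = batch_schedule(150, "2d", "initial")
        assert size == 150

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            batch_schedule(0)
        with pytest.raises(ValueError):
            batch_schedule(100, mode="4d")
        with pytest.raises(ValueError):
            batch_schedule(100, stage="middle")


class TestBlobInit:
    def test_deterministic_and_distinct(self):
        a = init_gaussian_blobs(4, 32, seed=9)
        b = init_gaussian_blobs(4, 32, seed=9)
        np.testing.assert_array_equal(a, b)
        for i in range(4):
            for j in range(i + 1, 4):
                ca, cb = a[i] - a[i].mean(), a[j] - a[j].mean()
                corr = (ca * cb).sum() / np.sqrt((ca ** 2).sum()
                                                 * (cb ** 2).sum())
                assert corr < 1.0 - 1e-6

    def test_blob_integral_matches_gaussian_mass(self):
        # 2 pi sigma_b^2 x amplitude, for blobs well inside the box
        blobs = init_gaussian_blobs(20, 64, seed=0)
        rng = np.random.default_rng(0)
        checked = 0
        for k in range(20):
            cy, cx = rng.uniform(-16, 16, size=2)
            width = rng.uniform(64 / 12, 64 / 7)
            if max(abs(cy), abs(cx)) + 3 * width < 32:   # well inside
                assert blobs[k].sum() == pytest.approx(
                    2 * np.pi * width ** 2, rel=0.02)
                checked += 1
        assert checked >= 5


class TestSubstitution:
    def _setup(self, K=4, box=8, seed=0):
        rng = np.random.default_rng(seed)
        cx = box // 2 + 1
        v1 = rng.standard_normal((K, box, cx)) + 0j
        v2 = rng.standard_normal((K, box, cx)) + 0j
        mom = MomentState.zeros(K, box)
        mom.m1 += rng.standard_normal((K, box, cx))
        mom.m2 += rng.standard_normal((K, box, cx))
        mom.u += rng.random((K, box, cx))
        gh1 = rng.standard_normal((K, box, cx)) + 0j
        gh2 = rng.standard_normal((K, box, cx)) + 0j
        fsc_vals = np.full((K, box // 2), 0.8)
        return v1, v2, mom, gh1, gh2, fsc_vals

    def test_no_substitution_at_uniform_mass(self):
        v1, v2, mom, gh1, gh2, fv = self._setup()
        mass = np.full(4, 0.25)
        out = substitute_inactive_class(v1, v2, mom, mass, rho=0.1,
                                        eps_sub=1e-8, ghat1=gh1, ghat2=gh2,
                                        fsc_values=fv, eta=0.5, eps2=1e-8)
        assert out is None

    def test_substitution_fires_below_threshold(self):
        v1, v2, mom, gh1, gh2, fv = self._setup()
        K, rho = 4, 0.1
        mass = np.array([0.4, 0.35, 0.24, 0.01])   # 0.01 < rho/K = 0.025
        v1_before = v1.copy()
        out = substitute_inactive_class(v1, v2, mom, mass, rho=rho,
                                        eps_sub=1e-8, ghat1=gh1, ghat2=gh2,
                                        fsc_values=fv, eta=0.5, eps2=1e-8)
        assert out is not None
        a, b = out
        assert a == 3 and b != a
        # a received b's one-step-ahead state: differs from both its old
        # self and from b's unchanged reference
        assert np.abs(v1[a] - v1_before[a]).max() > 1e-8
        assert np.abs(v1[a] - v1[b]).max() > 1e-10
        np.testing.assert_array_equal(v1[b], v1_before[b])

    def test_class_count_conserved_end_to_end(self):
        classes = make_classes(3, 32, seed=5)
        stack, truth = simulate_particles(classes, 400, seed=11)
        cfg = VdamConfig(n_classes=5, n_batches=25, seed=2,
                         batch_size_override=200)
        model, assign, log = run_vdam(stack, cfg)
        assert model.n_classes == 5
        assert len(model.class_probs) == 5
        assert model.class_probs.sum() == pytest.approx(1.0, abs=1e-9)


class TestRunVdam:
    def test_zero_batches_returns_initialization(self):
        classes = make_classes(2, 32, seed=3)
        stack, _ = simulate_particles(classes, 60, seed=5)
        cfg = VdamConfig(n_classes=2, n_batches=0, seed=7)
        model, assign, log = run_vdam(stack, cfg)
        from cryoclass.model import init_gaussian_blobs
        from cryoclass.grids import rfft_image
        g = fourier_grid(32)
        blobs = init_gaussian_blobs(2, 32, seed=7)
        expected = rfft_image(blobs)
        expected[:, ~g.active_half] = 0
        np.testing.assert_allclose(model.v1, expected, atol=1e-12)
        assert len(assign) == 60
        assert len(log) == 0

    def test_zero_eta_leaves_model_invariant(self):
        classes = make_classes(2, 32, seed=3)
        stack, _ = simulate_particles(classes, 200, seed=5)
        cfg = VdamConfig(n_classes=2, n_batches=6, seed=7, eta_override=0.0,
                         rho=0.0, batch_size_override=100)
        model, _, _ = run_vdam(stack, cfg)
        from cryoclass.model import init_gaussian_blobs
        from cryoclass.grids import rfft_image
        g = fourier_grid(32)
        expected = rfft_image(init_gaussian_blobs(2, 32, seed=7))
        expected[:, ~g.active_half] = 0
        np.testing.assert_allclose(model.v1, expected, atol=1e-12)

    def test_single_class_low_noise_recovery(self):
        from cryoclass.likelihood import NoiseSpectrum
        classes = make_classes(1, 32, seed=2)
        spec = NoiseSpectrum(np.full(16, 1e-3))

        def grid_poses(rng, n):
            return (rng.integers(0, 4, n) * 90.0,
                    rng.integers(-2, 3, (n, 2)).astype(float))

        stack, _ = simulate_particles(classes, 220, seed=4,
                                      noise_spectrum=spec,
                                      pose_sampler=grid_poses)
        cfg = VdamConfig(n_classes=1, n_batches=40, seed=0, fix_sigma=spec)
        model, _, _ = run_vdam(stack, cfg)
        avg = model.class_averages()[0]
        from tests.conftest import best_alignment_correlation
        assert best_alignment_correlation(classes[0], avg) > 0.99

    def test_determinism_under_seed(self):
        classes = make_classes(2, 32, seed=3)
        stack, _ = simulate_particles(classes, 200, seed=5)
        cfg1 = VdamConfig(n_classes=2, n_batches=8, seed=3,
                          batch_size_override=100)
        cfg2 = VdamConfig(n_classes=2, n_batches=8, seed=3,
                          batch_size_override=100)
        m1, a1, _ = run_vdam(stack, cfg1)
        m2, a2, _ = run_vdam(stack, cfg2)
        np.testing.assert_array_equal(m1.v1, m2.v1)
        assert (a1["rlnClassNumber"] == a2["rlnClassNumber"]).all()


class TestOptimizerEquivalence:
    def test_em_equals_single_full_batch_vmgd_iteration(self):
        """One EM iteration and one full-batch VMGD mini-batch at eta = 1
        produce the same references when sharing init and noise model."""
        from cryoclass.em import EmConfig, run_em
        from cryoclass.engine import data_power_sigma
        from cryoclass.likelihood import NoiseSpectrum

        classes = make_classes(2, 32, seed=3)
        stack, _ = simulate_particles(classes, 120, seed=6)
        sigma0 = data_power_sigma(stack.fourier_half())
        em_cfg = EmConfig(n_classes=2, n_iterations=1, seed=5,
                          fix_sigma=sigma0, truncation_fraction=1.0)
        em_model, _ = run_em(stack, em_cfg)
        vd_cfg = VdamConfig(n_classes=2, n_batches=1, seed=5,
                            update_rule="vmgd", eta_override=1.0,
                            batch_size_override=120, fix_sigma=sigma0,
                            truncation_fraction=1.0, rho=0.0)
        vd_model, _, _ = run_vdam(stack, vd_cfg)
        scale = np.abs(em_model.v1).max()
        assert np.abs(em_model.v1 - vd_model.v1).max() < 1e-4 * scale
        assert np.abs(em_model.v2 - vd_model.v2).max() < 1e-4 * scale
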