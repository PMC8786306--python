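"""Likelihood evaluation, posteriors, sufficient statistics and gradient,
cross-checked against brute-force full-plane oracles.

The toy problems use 90-degree rotation grids, where the interpolation
operator is an exact permutation and all analytic identities hold to
floating-point precision.
"""

import numpy as np
import pytest

from cryoclass.ctf import ctf_eval
from cryoclass.em import em_update
from cryoclass.grids import fourier_grid
from cryoclass.likelihood import (NoiseSpectrum, PosteriorField, SignalPrior,
                                  accumulate_stats, compute_posteriors,
                                  estimate_sigma, gradient, log_likelihood,
                                  pose_log_likelihoods, rotate_references,
                                  truncate_posteriors)
from cryoclass.transform import FourierImage, Pose, adjoint_transform


def _oracle_ll_table(tp):
    """Brute-force per-pose log-likelihoods via the full-plane path."""
    g, grid, sigma = tp["g"], tp["grid"], tp["sigma"]
    box = tp["box"]
    B, K = len(tp["imgs"]), len(tp["refs"])
    kyf = g.ky_full / (box * 2.0)
    kxf = g.kx_full / (box * 2.0)
    out = np.empty((B, K, grid.n_rot, grid.n_trans))
    for i in range(B):
        xF = FourierImage.from_real(tp["imgs"][i])
        cF = ctf_eval(tp["params"][i], kyf, kxf)
        for k in range(K):
            vF = FourierImage.from_real(tp["refs"][k])
            for r, psi in enumerate(grid.psis):
                for t, (tx, ty) in enumerate(grid.translations):
                    out[i, k, r, t] = log_likelihood(
                        xF, vF, Pose(float(psi), tx, ty), cF, sigma)
    return out


class TestLogLikelihood:
    def test_zero_residual_gives_pure_normalization(self, toy_problem):
        tp = toy_problem
        g, sigma = tp["g"], tp["sigma"]
        v = FourierImage.from_real(tp["refs"][0])
        pose = Pose(90.0, 1.0, -1.0)
        hv = (lambda p: p)(None)
        from cryoclass.transform import apply_transform
        x = apply_transform(v, pose, 1.0)
        val = log_likelihood(x, v, pose, 1.0, sigma)
        s2 = np.asarray(sigma.sigma2)[g.shell_full]
        expected = -float(np.sum(np.log(np.pi * s2[g.active_full])))
        assert val == pytest.approx(expected, rel=1e-12)
        # maximal over data: any other x scores lower
        x2 = FourierImage(x.coefficients + 0.1)
        assert log_likelihood(x2, v, pose, 1.0, sigma) < val

    def test_doubling_sigma2_rescales_terms(self, toy_problem):
        tp = toy_problem
        g = tp["g"]
        x = FourierImage.from_real(tp["imgs"][0])
        v = FourierImage.from_real(tp["refs"][0])
        pose = Pose(0.0)
        s1 = tp["sigma"]
        s2 = NoiseSpectrum(2.0 * s1.sigma2)
        l1 = log_likelihood(x, v, pose, 1.0, s1)
        l2 = log_likelihood(x, v, pose, 1.0, s2)
        n_act = int(g.active_full.sum())
        norm1 = np.sum(np.log(np.pi * s1.sigma2[g.shell_full][g.active_full]))
        quad1 = -l1 - norm1
        # quadratic halves, normalization gains n*log 2
        assert l2 == pytest.approx(-(quad1 / 2) - norm1 - n_act * np.log(2),
                                   rel=1e-10)

    def test_fast_path_matches_brute_force_summation(self, toy_problem):
        tp = toy_problem
        rr = rotate_references(tp["vh"], tp["grid"].psis, tp["box"],
                               dtype=np.complex128)
        ll = pose_log_likelihoods(tp["xh"], tp["ch"], rr, tp["grid"],
                                  tp["sigma"])
        oracle = _oracle_ll_table(tp)
        np.testing.assert_allclose(ll, oracle, rtol=1e-7)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpectrum(np.array([1.0, 0.0, 1.0]))


class TestPosteriors:
    def test_single_class_single_pose_weight_is_one(self, toy_problem):
        tp = toy_problem
        from cryoclass.transform import make_pose_grid
        grid1 = make_pose_grid(360.0, 0, 1, 2.0)
        rr = rotate_references(tp["vh"][:1], grid1.psis, tp["box"],
                               dtype=np.complex128)
        ll = pose_log_likelihoods(tp["xh"], tp["ch"], rr, grid1, tp["sigma"])
        post = compute_posteriors(ll, grid1)
        np.testing.assert_allclose(post.weights, 1.0, atol=1e-12)

    def test_identical_classes_split_mass_equally(self, toy_problem):
        tp = toy_problem
        vh2 = np.stack([tp["vh"][0], tp["vh"][0]])
        rr = rotate_references(vh2, tp["grid"].psis, tp["box"],
                               dtype=np.complex128)
        ll = pose_log_likelihoods(tp["xh"], tp["ch"], rr, tp["grid"],
                                  tp["sigma"])
        post = compute_posteriors(ll, tp["grid"])
        np.testing.assert_allclose(post.per_particle_class, 0.5, atol=1e-12)

    def test_matches_direct_enumeration(self, toy_problem):
        tp = toy_problem
        oracle_ll = _oracle_ll_table(tp)
        K = oracle_ll.shape[1]
        logw = oracle_ll + np.log(tp["grid"].prior).reshape(
            1, 1, tp["grid"].n_rot, tp["grid"].n_trans) - np.log(K)
        B = logw.shape[0]
        flat = logw.reshape(B, -1)
        m = flat.max(1, keepdims=True)
        w = np.exp(flat - m)
        oracle_post = (w / w.sum(1, keepdims=True)).reshape(oracle_ll.shape)
        rr = rotate_references(tp["vh"], tp["grid"].psis, tp["box"],
                               dtype=np.complex128)
        ll = pose_log_likelihoods(tp["xh"], tp["ch"], rr, tp["grid"],
                                  tp["sigma"])
        post = compute_posteriors(ll, tp["grid"])
        np.testing.assert_allclose(post.weights, oracle_post, atol=1e-7)

    def test_normalization_exact(self, toy_problem):
        tp = toy_problem
        rr = rotate_references(tp["vh"], tp["grid"].psis, tp["box"],
                               dtype=np.complex128)
        ll = pose_log_likelihoods(tp["xh"], tp["ch"], rr, tp["grid"],
                                  tp["sigma"])
        post = compute_posteriors(ll, tp["grid"])
        sums = post.weights.reshape(len(tp["imgs"]), -1).sum(1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_evidence_invariant_to_particle_order_and_relabeling(self, toy_problem):
        tp = toy_problem
        rr = rotate_references(tp["vh"], tp["grid"].psis, tp["box"],
                               dtype=np.complex128)
        ll = pose_log_likelihoods(tp["xh"], tp["ch"], rr, tp["grid"],
                                  tp["sigma"])
        post = compute_posteriors(ll, tp["grid"])
        total = post.log_evidence.sum()
        # particle order
        perm = np.array([2, 0, 1])
        post_p = compute_posteriors(ll[perm], tp["grid"])
        assert post_p.log_evidence.sum() == pytest.approx(total, rel=1e-14)
        # class relabeling with matching weight relabeling
        post_r = compute_posteriors(ll[:, ::-1], tp["grid"])
        assert post_r.log_evidence.sum() == pytest.approx(total, rel=1e-14)


class TestStatsAndGradient:
    def _posteriors(self, tp):
        rr = rotate_references(tp["vh"], tp["grid"].psis, tp["box"],
                               dtype=np.complex128)
        ll = pose_log_likelihoods(tp["xh"], tp["ch"], rr, tp["grid"],
                                  tp["sigma"])
        return compute_posteriors(ll, tp["grid"]), rr

    def test_stats_match_brute_force_adjoint_loop(self, toy_problem):
        tp = toy_problem
        g, box = tp["g"], tp["box"]
        post, _ = self._posteriors(tp)
        stats = accumulate_stats(tp["xh"], tp["ch"], post, tp["grid"],
                                 tp["sigma"])
        kyf = g.ky_full / (box * 2.0)
        kxf = g.kx_full / (box * 2.0)
        s2f = np.asarray(tp["sigma"].sigma2)[g.shell_full]
        K = len(tp["refs"])
        b_oracle = np.zeros((K, box, box), complex)
        for i in range(len(tp["imgs"])):
            xF = FourierImage.from_real(tp["imgs"][i])
            cF = np.where(g.active_full,
                          ctf_eval(tp["params"][i], kyf, kxf), 0)
            xw = FourierImage(np.where(g.active_full,
                                       xF.coefficients / s2f, 0))
            for k in range(K):
                for r, psi in enumerate(tp["grid"].psis):
                    for t, (tx, ty) in enumerate(tp["grid"].translations):
                        w = float(post.weights[i, k, r, t])
                        if w == 0:
                            continue
                        b_oracle[k] += w * adjoint_transform(
                            xw, Pose(float(psi), tx, ty), cF).coefficients
        cx = box // 2 + 1
        m = g.active_half
        np.testing.assert_allclose(stats.b[:, m],
                                   b_oracle[:, :, :cx][:, m], rtol=1e-6)
        assert stats.mass.sum() == pytest.approx(len(tp["imgs"]), abs=1e-9)
        assert np.all(stats.f >= 0)

    def test_stats_additive_over_duplicate_particles(self, toy_problem):
        tp = toy_problem
        post, _ = self._posteriors(tp)
        stats1 = accumulate_stats(tp["xh"], tp["ch"], post, tp["grid"],
                                  tp["sigma"])
        xh2 = np.concatenate([tp["xh"], tp["xh"]])
        ch2 = np.concatenate([tp["ch"], tp["ch"]])
        post2 = PosteriorField(np.concatenate([post.weights, post.weights]),
                               np.concatenate([post.log_evidence] * 2))
        stats2 = accumulate_stats(xh2, ch2, post2, tp["grid"], tp["sigma"])
        np.testing.assert_allclose(stats2.b, 2 * stats1.b, rtol=1e-12)
        np.testing.assert_allclose(stats2.f, 2 * stats1.f, rtol=1e-12)

    def test_concentrated_identity_pose_gives_direct_stats(self, toy_problem):
        # posterior mass all on the identity pose with CTF == 1:
        # B = x / sigma^2, F = 1 / sigma^2
        tp = toy_problem
        g = tp["g"]
        from cryoclass.transform import make_pose_grid
        grid1 = make_pose_grid(360.0, 0, 1, 2.0)
        w = np.ones((1, 1, 1, 1), np.float64)
        post = PosteriorField(w, np.zeros(1))
        ones = np.where(g.active_half, 1.0, 0.0)[None]
        stats = accumulate_stats(tp["xh"][:1], ones, post, grid1, tp["sigma"])
        w0 = np.where(g.active_half, 1.0 / tp["sigma"].sigma2[g.shell_half], 0)
        np.testing.assert_allclose(stats.b[0], tp["xh"][0] * w0, atol=1e-12)
        np.testing.assert_allclose(stats.f[0], w0, atol=1e-12)

    def test_gradient_matches_finite_differences(self, toy_problem):
        tp = toy_problem
        g, box = tp["g"], tp["box"]
        grid, sigma = tp["grid"], tp["sigma"]
        K = len(tp["refs"])
        tau = SignalPrior(np.full(g.n_shells, 2.0))

        def objective(refs_real):
            from cryoclass.grids import rfft_image
            vv = rfft_image(refs_real).astype(np.complex128)
            vv[..., ~g.active_half] = 0
            rr = rotate_references(vv, grid.psis, box, dtype=np.complex128)
            ll = pose_log_likelihoods(tp["xh"], tp["ch"], rr, grid, sigma)
            lp = grid.log_prior().reshape(1, 1, grid.n_rot, -1)
            flat = (ll + lp - np.log(K)).reshape(ll.shape[0], -1)
            m = flat.max(1, keepdims=True)
            le = (m[:, 0] + np.log(np.exp(flat - m).sum(1))).sum()
            pr = sum(np.sum(g.mult_act
                            * (-np.abs(g.pack(vv[k])) ** 2
                               / tau.tau2[g.shell_act]))
                     for k in range(K))
            return le + pr

        post, _ = self._posteriors(tp)
        stats = accumulate_stats(tp["xh"], tp["ch"], post, grid, sigma)
        grad = gradient(stats, tp["vh"], tau)
        rng = np.random.default_rng(11)
        eps = 1e-5
        for _ in range(3):
            d = rng.standard_normal((K, box, box)) * 0.5
            fd = (objective(tp["refs"] + eps * d)
                  - objective(tp["refs"] - eps * d)) / (2 * eps)
            from cryoclass.grids import rfft_image
            dv = rfft_image(d)
            dv[..., ~g.active_half] = 0
            analytic = np.sum(g.mult_half[None] * 2
                              * np.real(grad * np.conj(dv)))
            assert abs(fd - analytic) / abs(fd) < 1e-4

    def test_em_fixed_point_zeroes_gradient(self, toy_problem):
        tp = toy_problem
        post, _ = self._posteriors(tp)
        stats = accumulate_stats(tp["xh"], tp["ch"], post, tp["grid"],
                                 tp["sigma"])
        tau = SignalPrior(np.full(tp["g"].n_shells, 2.0))
        v_star = em_update(stats, tau)
        g0 = gradient(stats, v_star, tau)
        assert np.abs(g0).max() < 1e-10

    def test_gradient_without_prior_at_zero_reference_is_b(self, toy_problem):
        tp = toy_problem
        post, _ = self._posteriors(tp)
        stats = accumulate_stats(tp["xh"], tp["ch"], post, tp["grid"],
                                 tp["sigma"])
        g0 = gradient(stats, np.zeros_like(tp["vh"]), None)
        np.testing.assert_allclose(g0, stats.b, atol=0)


class TestTruncation:
    def test_full_fraction_is_identity(self, toy_problem):
        tp = toy_problem
        rr = rotate_references(tp["vh"], tp["grid"].psis, tp["box"],
                               dtype=np.complex128)
        ll = pose_log_likelihoods(tp["xh"], tp["ch"], rr, tp["grid"],
                                  tp["sigma"])
        post = compute_posteriors(ll, tp["grid"])
        out = truncate_posteriors(post, 1.0)
        np.testing.assert_array_equal(out.weights, post.weights)

    def test_small_example_arithmetic(self):
        w = np.array([0.7, 0.2, 0.1]).reshape(1, 1, 1, 3)
        post = PosteriorField(w, np.zeros(1))
        out = truncate_posteriors(post, 0.8)
        np.testing.assert_allclose(out.weights.ravel(),
                                   [7 / 9, 2 / 9, 0.0], rtol=1e-12)

    def test_high_fraction_barely_changes_stats(self, toy_problem):
        tp = toy_problem
        rr = rotate_references(tp["vh"], tp["grid"].psis, tp["box"],
                               dtype=np.complex128)
        ll = pose_log_likelihoods(tp["xh"], tp["ch"], rr, tp["grid"],
                                  tp["sigma"])
        post = compute_posteriors(ll, tp["grid"])
        full = accumulate_stats(tp["xh"], tp["ch"], post, tp["grid"],
                                tp["sigma"])
        trunc = accumulate_stats(tp["xh"], tp["ch"],
                                 truncate_posteriors(post, 0.999),
                                 tp["grid"], tp["sigma"])
        rel_b = np.abs(trunc.b - full.b).max() / np.abs(full.b).max()
        rel_f = np.abs(trunc.f - full.f).max() / np.abs(full.f).max()
        assert rel_b <= 0.005 and rel_f <= 0.005

    def test_invalid_fraction_raises(self, toy_problem):
        post = PosteriorField(np.ones((1, 1, 1, 1)), np.zeros(1))
        with pytest.raises(ValueError):
            truncate_posteriors(post, 0.0)


class TestSigmaEstimation:
    def test_flat_noise_recovery(self):
        # pure noise, v = 0: per-shell residual power recovers sigma^2
        rng = np.random.default_rng(3)
        box = 16
        g = fourier_grid(box)
        from cryoclass.grids import rfft_image
        c = 2.0
        n = 500
        noise = rfft_image(rng.standard_normal((n, box, box))) * np.sqrt(c)
        power = np.zeros(g.n_shells)
        for i in range(n):
            power += g.shell_sum(g.pack(np.abs(noise[i]) ** 2))
        est = estimate_sigma(power, g.shell_counts * n)
        assert np.all(np.abs(est.sigma2 / c - 1.0) < 0.05)

    def test_scaling_quadratic(self):
        power = np.array([4.0, 8.0, 12.0])
        counts = np.array([2.0, 2.0, 2.0])
        a = estimate_sigma(power, counts).sigma2
        b = estimate_sigma(4 * power, counts).sigma2
        np.testing.assert_allclose(b, 4 * a)

    def test_zero_residuals_floored(self):
        est = estimate_sigma(np.zeros(4), np.ones(4))
        assert np.all(est.sigma2 > 0)
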