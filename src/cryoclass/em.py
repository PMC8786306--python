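"""Classical Expectation-Maximization optimizer for 2D classification.

Each iteration runs a full E-step per half-set (posteriors over classes
and grid poses), accumulates the sufficient statistics B_k, F_k and
applies the closed-form regularized update

    v_k <- B_k / (F_k + tau^-2)     (element-wise)

per half.  The noise spectrum sigma^2(s) is re-estimated from
posterior-weighted residuals and the signal prior tau^2(s) from the
half-set FSC each iteration (both can be frozen, e.g. to check the EM
monotonicity guarantee, which holds for fixed sigma, tau and full
marginalization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .engine import (data_power_sigma, estep, final_pass, half_indices,
                     prior_objective)
from .grids import fourier_grid
from .likelihood import (NoiseSpectrum, SignalPrior, SufficientStats,
                         accumulate_stats, estimate_sigma, residual_shell_power,
                         truncate_posteriors)
from .model import (ClassModel, estimate_tau, fsc, init_gaussian_blobs,
                    resolution_from_fsc)
from .transform import make_pose_grid

logger = logging.getLogger(__name__)

__all__ = ["EmConfig", "em_update", "run_em"]


@dataclass
class EmConfig:
    """Settings for :func:`run_em`."""

    n_classes: int = 3
    n_iterations: int = 25
    angular_step: float = 15.0
    max_translation: int = 3
    translation_step: int = 1
    translation_sigma: float = 2.0
    truncation_fraction: float = 0.999   # applied from the 2nd iteration
    seed: int = 0
    fix_sigma: NoiseSpectrum | None = None
    fix_tau: np.ndarray | None = None    # (K, n_shells) or None
    initial_references: np.ndarray | None = None  # real-space (K, box, box)
    double_precision: bool = False       # exact float64 E-step (slower)
    keep_history: bool = True
    history: list = field(default_factory=list)


def em_update(stats: SufficientStats, tau: SignalPrior | None) -> np.ndarray:
    """Maximization step: v = B / (F + tau^-2), element-wise.

    ``tau`` is per-shell (or None for no regularization).  Elements where
    the denominator vanishes (no data weight and no regularization) are
    set to 0 with a logged warning.
    """
    box = stats.f.shape[-2]
    g = fourier_grid(box)
    if tau is None:
        inv_tau2 = np.zeros(stats.f.shape[-2:])
    else:
        inv_tau2 = np.where(g.active_half, tau.inv()[..., g.shell_half], 0.0)
    denom = stats.f + inv_tau2
    zero = (denom == 0) & g.active_half
    if np.any(zero):
        logger.warning("em_update: %d elements with zero denominator set to 0",
                       int(zero.sum()))
    out = np.divide(stats.b, denom, out=np.zeros_like(stats.b),
                    where=denom > 0)
    out[..., ~g.active_half] = 0.0
    return out


def _tau_priors(model: ClassModel, cfg: EmConfig,
                f_half: np.ndarray | None) -> list[SignalPrior | None]:
    K = cfg.n_classes
    if cfg.fix_tau is not None:
        return [SignalPrior(cfg.fix_tau[k]) for k in range(K)]
    if model.tau2 is None:
        return [None] * K   # first iteration: unregularized
    return [SignalPrior(model.tau2[k]) for k in range(K)]


def run_em(stack, config: EmConfig | None = None):
    """Run EM 2D classification on a :class:`~cryoclass.particles.ParticleStack`.

    Returns (ClassModel, assignments DataFrame).  ``config.history``
    collects one record per iteration (evidence, objective, class masses).
    """
    cfg = config or EmConfig()
    K = cfg.n_classes
    box = stack.box
    g = fourier_grid(box)
    grid = make_pose_grid(cfg.angular_step, cfg.max_translation,
                          cfg.translation_step, cfg.translation_sigma, box=box)
    xh = stack.fourier_half()
    ch = stack.ctf_half()
    if cfg.double_precision:
        xh = xh.astype(np.complex128)
        ch = ch.astype(np.float64)
    idx1, idx2 = half_indices(stack.halfset)

    if cfg.initial_references is None:
        refs = init_gaussian_blobs(K, box, seed=cfg.seed)
    else:
        refs = np.asarray(cfg.initial_references, dtype=np.float64)
    sigma = cfg.fix_sigma or data_power_sigma(xh)
    model = ClassModel.from_real_references(refs, stack.pixel_size, sigma)
    if cfg.fix_tau is not None:
        model.tau2 = np.asarray(cfg.fix_tau, dtype=np.float64)

    for it in range(cfg.n_iterations):
        taus = _tau_priors(model, cfg, None)
        evidence = 0.0
        stats_halves: list[SufficientStats] = []
        resid_power = np.zeros(g.n_shells)
        resid_counts = np.zeros(g.n_shells)
        for idx, v_h in ((idx1, model.v1), (idx2, model.v2)):
            post, rot_refs = estep(xh[idx], ch[idx], v_h, grid, model.sigma)
            evidence += float(post.log_evidence.sum())
            if it > 0 and cfg.truncation_fraction < 1.0:
                post = truncate_posteriors(post, cfg.truncation_fraction)
            stats_halves.append(accumulate_stats(xh[idx], ch[idx], post, grid,
                                                 model.sigma, K=K))
            if cfg.fix_sigma is None:
                p, c = residual_shell_power(xh[idx], ch[idx], rot_refs, post, grid)
                resid_power += p
                resid_counts += c
        # M-step per half
        new_v = []
        for stats, taus_k in ((stats_halves[0], taus), (stats_halves[1], taus)):
            vk = np.empty_like(model.v1)
            for k in range(K):
                sk = SufficientStats(stats.b[k:k + 1], stats.f[k:k + 1],
                                     stats.mass[k:k + 1], stats.n_particles)
                vk[k] = em_update(sk, taus_k[k])[0]
            new_v.append(vk)
        model.v1, model.v2 = new_v

        # spectra re-estimation
        curves = [fsc(model.v1[k], model.v2[k], min_coeffs=3) for k in range(K)]
        model.fsc_curves = curves
        if cfg.fix_tau is None:
            f_mean = 0.5 * (stats_halves[0].f + stats_halves[1].f)
            model.tau2 = np.stack([estimate_tau(curves[k], f_mean[k]).tau2
                                   for k in range(K)])
        if cfg.fix_sigma is None:
            model.sigma = estimate_sigma(resid_power, resid_counts)

        mass = stats_halves[0].mass + stats_halves[1].mass
        objective = evidence
        if model.tau2 is not None:
            objective += prior_objective(np.asarray(model.combined), model.tau2)
        if not np.isfinite(evidence):
            raise FloatingPointError(f"non-finite evidence at iteration {it}: "
                                     f"{evidence}; class masses {mass}")
        if cfg.keep_history:
            cfg.history.append({"iteration": it, "evidence": evidence,
                                "objective": objective,
                                "class_mass": mass / mass.sum()})
        logger.info("EM iter %d: evidence %.6g", it, evidence)

    res = final_pass(xh, ch, model.combined, grid, model.sigma)
    model.class_probs = res["class_probs"]
    model.acc_rot, model.acc_trans = res["acc_rot"], res["acc_trans"]
    model.resolution = np.array([
        resolution_from_fsc(c, box, stack.pixel_size) for c in model.fsc_curves
    ]) if model.fsc_curves else None
    return model, res["assignments"]
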