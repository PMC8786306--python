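"""Variable-metric gradient descent with adaptive moments (VDAM).

The Expectation-Maximization update v <- B/(F + tau^-2) can be written as
a gradient-descent step preconditioned by the diagonal variable metric
D = diag[(F + tau^-2)^-1]:

    v <- v - eta * (G + tau^-2 v) / (F + tau^-2),     G := F . v - B,

where G is the negative data-term gradient; with eta = 1 on a full batch
this reproduces the EM update exactly.  Replacing tau^-2 by the half-set
FSC (SNR = FSC/(1-FSC)) turns the step into

    v <- v - eta * [ FSC * G/(F + eps1) + (1 - FSC) * v ].

VDAM runs this on mini-batches with Adam-style running moments of the
rescaled gradient Ghat = G/(F + eps1) (invariant to batch size): separate
first moments for the two half-sets, and a shared second moment tracking
|Ghat_h1 - Ghat_h2|^2, an estimate of the gradient's noise amplitude:

    m_h <- beta1 m_h + (1 - beta1) Ghat_h          (beta1 = 0.9)
    u   <- beta2 u   + (1 - beta2) |Ghat_h1 - Ghat_h2|^2   (beta2 = 0.999)
    v_h <- v_h - eta [ FSC * m_h / (sqrt(u) + eps2) + (1 - FSC) v_h ].

Classes whose (running) likelihood probability P(X|k) falls below rho/K
are replaced by a one-step-ahead copy of the class whose moments are
changing the most (largest |m/(u + eps)|^2).

Mini-batch schedule (2D classification): an initial stage with batch size
clamp(0.005 N, 200, 10000) at learning rate 0.9, then
clamp(0.05 N, 1000, 100000) at 0.3 (3D initial-model constants: maxima
5000 / 50000, 10% later fraction, later rate 0.5).  The default run
length is 200 mini-batches; a final full pass computes only P(X|k) and
per-particle assignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (data_power_sigma, estep, final_pass, half_indices)
from .grids import fourier_grid
from .likelihood import (NoiseSpectrum, SufficientStats, accumulate_stats,
                         estimate_sigma, gradient, residual_shell_power,
                         truncate_posteriors)
from .model import ClassModel, FscCurve, fsc, init_gaussian_blobs, resolution_from_fsc
from .transform import make_pose_grid

logger = logging.getLogger(__name__)

__all__ = ["VdamConfig", "MomentState", "rescaled_gradient", "vmgd_update",
           "update_moments", "vdam_update", "batch_schedule",
           "substitute_inactive_class", "init_gaussian_blobs", "run_vdam"]


# --------------------------------------------------------------------------
# elementary updates
# --------------------------------------------------------------------------

def rescaled_gradient(g: np.ndarray, f: np.ndarray, eps1: float) -> np.ndarray:
    """Ghat = G / (F + eps1): invariant to mini-batch size (G and F both
    scale with the number of particles)."""
    return g / (f + eps1)


def vmgd_update(v: np.ndarray, g: np.ndarray, f: np.ndarray,
                inv_tau2: np.ndarray | float, eta: float) -> np.ndarray:
    """Variable-metric gradient-descent step.

    v <- v - eta (G + tau^-2 v) / (F + tau^-2); with eta = 1 and full-batch
    G = F.v - B this equals the EM update B/(F + tau^-2) exactly.
    """
    denom = f + inv_tau2
    step = np.divide(g + inv_tau2 * v, denom,
                     out=np.zeros_like(v), where=denom > 0)
    return v - eta * step


@dataclass
class MomentState:
    """Per-class running averages: first moments per half, shared second."""

    m1: np.ndarray   # (K, box, box//2+1) complex
    m2: np.ndarray
    u: np.ndarray    # (K, box, box//2+1) real, >= 0

    @classmethod
    def zeros(cls, K: int, box: int) -> "MomentState":
        shape = (K, box, box // 2 + 1)
        return cls(m1=np.zeros(shape, np.complex128),
                   m2=np.zeros(shape, np.complex128),
                   u=np.zeros(shape, np.float64))


def update_moments(state: MomentState, ghat1: np.ndarray, ghat2: np.ndarray,
                   beta1: float = 0.9, beta2: float = 0.999) -> MomentState:
    """Adaptive-moment recursions (applied per class, returns new state)."""
    m1 = beta1 * state.m1 + (1.0 - beta1) * ghat1
    m2 = beta1 * state.m2 + (1.0 - beta1) * ghat2
    u = beta2 * state.u + (1.0 - beta2) * np.abs(ghat1 - ghat2) ** 2
    return MomentState(m1=m1, m2=m2, u=u)


def vdam_update(v_h: np.ndarray, m_h: np.ndarray, u: np.ndarray,
                fsc_curve: FscCurve | np.ndarray, eta: float,
                eps2: float, bias2: float = 1.0) -> np.ndarray:
    """Adaptive-moment update of one half-set reference.

    v_h <- v_h - eta [FSC m_h / (sqrt(u / bias2) + eps2) + (1 - FSC) v_h],
    with the per-shell FSC clipped to [0, 1] and broadcast onto the
    frequency grid.

    ``bias2`` = 1 - beta2^n removes the initialization bias of the running
    second moment (which starts at zero), as in the Adam family; the
    driver supplies it, the default leaves the printed recursion as is.
    The data-term multiplier eta FSC/(sqrt(u/bias2) + eps2) is clipped at
    1: the rescaled-gradient moment m already has the magnitude of the
    preconditioned (EM-equivalent) displacement, so a larger multiplier
    would overshoot the EM step that the variable metric is derived to
    reproduce.  The clip only engages when the half-set gradient noise
    sqrt(u) is small relative to the learning rate (high-SNR regimes).
    """
    box = v_h.shape[-2]
    g = fourier_grid(box)
    vals = fsc_curve.values if isinstance(fsc_curve, FscCurve) else np.asarray(fsc_curve)
    c = np.clip(vals, 0.0, 1.0)[..., g.shell_half]
    mult = np.minimum(eta * c / (np.sqrt(u / bias2) + eps2), 1.0)
    return v_h - mult * m_h - eta * (1.0 - c) * v_h


def batch_schedule(n_particles: int, mode: str = "2d",
                   stage: str = "initial") -> tuple[int, float]:
    """Mini-batch size and learning rate for a dataset of N particles.

    2D initial: clamp(0.005 N, 200, 10000), eta 0.9;
    2D later:   clamp(0.05 N, 1000, 100000), eta 0.3;
    3D initial: clamp(0.005 N, 200, 5000),   eta 0.9;
    3D later:   clamp(0.10 N, 1000, 50000),  eta 0.5.
    Batch size never exceeds N.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if mode not in ("2d", "3d"):
        raise ValueError(f"mode must be '2d' or '3d', got {mode}")
    if stage not in ("initial", "later"):
        raise ValueError(f"stage must be 'initial' or 'later', got {stage}")
    if stage == "initial":
        frac, lo, hi = 0.005, 200, (10000 if mode == "2d" else 5000)
        eta = 0.9
    else:
        if mode == "2d":
            frac, lo, hi, eta = 0.05, 1000, 100000, 0.3
        else:
            frac, lo, hi, eta = 0.10, 1000, 50000, 0.5
    size = int(min(max(frac * n_particles, lo), hi))
    return min(size, n_particles), eta


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class VdamConfig:
    """Settings for :func:`run_vdam`."""

    n_classes: int = 3
    n_batches: int = 200
    mode: str = "2d"
    beta1: float = 0.9
    beta2: float = 0.999
    rho: float = 0.1                   # class inactivity threshold
    eps1: float | None = None          # None -> 1e-8 * mean(F) of first batch
    eps2: float | None = None
    eps_sub: float | None = None
    angular_step: float = 15.0
    max_translation: int = 3
    translation_step: int = 1
    translation_sigma: float = 2.0
    truncation_fraction: float = 0.999  # applied after the first 10 batches
    truncation_start: int = 10
    prune_rotations: int | None = None  # None: auto (KR//4, min 16) after start
    sigma_refresh: int = 25
    substitution_cooldown: int = 10
    eta_ramp: int = 10                 # batches of linear eta ramp at the switch
    initial_stage_fraction: float = 0.25
    seed: int = 0
    update_rule: str = "vdam"          # or "vmgd" (Eq-11-style, no moments)
    eta_override: float | None = None
    batch_size_override: int | None = None
    fix_sigma: NoiseSpectrum | None = None
    initial_references: np.ndarray | None = None
    keep_log: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta1 < 1.0 and 0.0 <= self.beta2 < 1.0):
            raise ValueError("beta1, beta2 must lie in [0, 1)")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.n_batches < 0:
            raise ValueError("n_batches must be >= 0")


# --------------------------------------------------------------------------
# class substitution
# --------------------------------------------------------------------------

def substitute_inactive_class(v1: np.ndarray, v2: np.ndarray,
                              moments: MomentState, class_mass: np.ndarray,
                              rho: float, eps_sub: float,
                              ghat1: np.ndarray, ghat2: np.ndarray,
                              fsc_values: np.ndarray, eta: float, eps2: float,
                              beta1: float = 0.9, beta2: float = 0.999,
                              eligible: np.ndarray | None = None,
                              bias2: float = 1.0
                              ) -> tuple[int, int] | None:
    """Replace the least-likely class by a fast-moving copy, in place.

    If the smallest class mass is below rho/K: class a (smallest P(X|k),
    restricted to ``eligible``) is given class b's references and moments
    advanced by one moment+reference update computed from b's current
    rescaled gradients, while b itself keeps its previous state (its
    normal update for this batch must be skipped by the caller).  Returns
    (a, b), or None if no substitution fired.

    ``ghat1``/``ghat2`` are the per-class rescaled half-set gradients of
    the current batch; ``fsc_values`` the (K, n_shells) FSC curves.
    """
    K = len(class_mass)
    if eligible is None:
        eligible = np.ones(K, dtype=bool)
    masses = np.where(eligible, class_mass, np.inf)
    a = int(np.argmin(masses))
    if not np.isfinite(masses[a]) or class_mass[a] >= rho / K:
        return None
    score = (np.abs(moments.m1 / (moments.u + eps_sub)) ** 2
             + np.abs(moments.m2 / (moments.u + eps_sub)) ** 2).reshape(K, -1).sum(axis=1)
    score[a] = -np.inf
    b = int(np.argmax(score))
    if b == a:
        return None
    sub_state = MomentState(m1=moments.m1[b:b + 1].copy(),
                            m2=moments.m2[b:b + 1].copy(),
                            u=moments.u[b:b + 1].copy())
    sub_state = update_moments(sub_state, ghat1[b:b + 1], ghat2[b:b + 1],
                               beta1, beta2)
    curve = fsc_values[b]
    v1[a] = vdam_update(v1[b], sub_state.m1[0], sub_state.u[0], curve, eta,
                        eps2, bias2=bias2)
    v2[a] = vdam_update(v2[b], sub_state.m2[0], sub_state.u[0], curve, eta,
                        eps2, bias2=bias2)
    moments.m1[a] = sub_state.m1[0]
    moments.m2[a] = sub_state.m2[0]
    moments.u[a] = sub_state.u[0]
    return a, b


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

class _HalfSampler:
    """Without-replacement sampling balanced across half-sets; each half is
    reshuffled independently when its epoch is exhausted."""

    def __init__(self, idx1: np.ndarray, idx2: np.ndarray,
                 rng: np.random.Generator):
        self.rng = rng
        self.pools = [idx1.copy(), idx2.copy()]
        self.queues = [self.rng.permutation(p) for p in self.pools]
        self.pos = [0, 0]

    def draw(self, n_per_half: list[int]) -> list[np.ndarray]:
        out = []
        for h in (0, 1):
            need = n_per_half[h]
            got: list[np.ndarray] = []
            while need > 0:
                avail = len(self.queues[h]) - self.pos[h]
                if avail == 0:
                    self.queues[h] = self.rng.permutation(self.pools[h])
                    self.pos[h] = 0
                    avail = len(self.queues[h])
                take = min(need, avail)
                got.append(self.queues[h][self.pos[h]:self.pos[h] + take])
                self.pos[h] += take
                need -= take
            out.append(np.concatenate(got) if got else np.array([], dtype=int))
        return out


def run_vdam(stack, config: VdamConfig | None = None):
    """Run VDAM 2D classification on a particle stack.

    Returns (ClassModel, assignments DataFrame, batch log DataFrame).
    """
    cfg = config or VdamConfig()
    K = cfg.n_classes
    box = stack.box
    N = len(stack)
    g = fourier_grid(box)
    grid = make_pose_grid(cfg.angular_step, cfg.max_translation,
                          cfg.translation_step, cfg.translation_sigma, box=box)
    rng = np.random.default_rng(cfg.seed)
    xh = stack.fourier_half()
    ch = stack.ctf_half()
    idx1, idx2 = half_indices(stack.halfset)
    sampler = _HalfSampler(idx1, idx2, rng)

    if cfg.initial_references is None:
        refs = init_gaussian_blobs(K, box, seed=cfg.seed)
    else:
        refs = np.asarray(cfg.initial_references, dtype=np.float64)
    sigma = cfg.fix_sigma or data_power_sigma(xh)
    model = ClassModel.from_real_references(refs, stack.pixel_size, sigma)
    moments = MomentState.zeros(K, box)
    n_updates = np.zeros(K, dtype=np.int64)   # per-class moment updates
    running_mass = np.full(K, 1.0 / K)
    eps1, eps2, eps_sub = cfg.eps1, cfg.eps2, cfg.eps_sub
    last_sub = np.full(K, -10**9)
    n_initial = max(int(round(cfg.initial_stage_fraction * cfg.n_batches)), 0)
    log_rows = []

    for n in range(cfg.n_batches):
        stage = "initial" if n < n_initial else "later"
        bs, eta = batch_schedule(N, cfg.mode, stage)
        if n_initial <= n < n_initial + cfg.eta_ramp:
            eta0 = batch_schedule(N, cfg.mode, "initial")[1]
            eta1 = batch_schedule(N, cfg.mode, "later")[1]
            eta = eta0 + (eta1 - eta0) * (n - n_initial + 1) / cfg.eta_ramp
        if cfg.batch_size_override is not None:
            bs = cfg.batch_size_override
        if cfg.eta_override is not None:
            eta = cfg.eta_override
        half_bs = [bs // 2, bs - bs // 2]
        batches = sampler.draw(half_bs)

        if n >= cfg.truncation_start and cfg.truncation_fraction < 1.0:
            keep_rot = cfg.prune_rotations
            if keep_rot is None:
                keep_rot = max(16, (K * grid.n_rot) // 4)
        else:
            keep_rot = None
        stats: list[SufficientStats] = []
        posts = []
        rot_refs_h = []
        evidence = 0.0
        for h, v_h in enumerate((model.v1, model.v2)):
            idx = batches[h]
            post, rot_refs = estep(xh[idx], ch[idx], v_h, grid, model.sigma,
                                   keep_rot=keep_rot)
            posts.append(post)
            rot_refs_h.append(rot_refs)
            evidence += float(post.log_evidence.sum())
        if (cfg.fix_sigma is None
                and (n == 0 or (cfg.sigma_refresh
                                and n % cfg.sigma_refresh == 0))):
            power = np.zeros(g.n_shells)
            counts = np.zeros(g.n_shells)
            for h in range(2):
                p, c = residual_shell_power(xh[batches[h]], ch[batches[h]],
                                            rot_refs_h[h], posts[h], grid)
                power += p
                counts += c
            model.sigma = estimate_sigma(power, counts)
            if n == 0:   # redo the first posteriors with the estimated noise
                posts = []
                evidence = 0.0
                for h, v_h in enumerate((model.v1, model.v2)):
                    idx = batches[h]
                    post, _ = estep(xh[idx], ch[idx], v_h, grid, model.sigma,
                                    rot_refs=rot_refs_h[h], keep_rot=keep_rot)
                    posts.append(post)
                    evidence += float(post.log_evidence.sum())
        for h in range(2):
            if n >= cfg.truncation_start and cfg.truncation_fraction < 1.0:
                posts[h] = truncate_posteriors(posts[h], cfg.truncation_fraction)
            stats.append(accumulate_stats(xh[batches[h]], ch[batches[h]],
                                          posts[h], grid, model.sigma, K=K))
        if eps1 is None:
            f_scale = float(np.mean([s.f[:, g.active_half].mean() for s in stats]))
            base = max(1e-8 * f_scale, np.finfo(np.float64).tiny)
            eps1 = base
            eps2 = eps2 if eps2 is not None else base
            eps_sub = eps_sub if eps_sub is not None else base

        ghat = []
        for h, (v_h, st) in enumerate(((model.v1, stats[0]), (model.v2, stats[1]))):
            g_data = st.f * v_h - st.b     # negative data-term gradient
            ghat.append(rescaled_gradient(g_data, st.f, eps1))

        batch_mass = (stats[0].mass + stats[1].mass) / bs
        running_mass = cfg.beta1 * running_mass + (1 - cfg.beta1) * batch_mass
        curves = [fsc(model.v1[k], model.v2[k], min_coeffs=3) for k in range(K)]
        fsc_vals = np.stack([c.values for c in curves])

        substituted = None
        skip = np.zeros(K, dtype=bool)
        if cfg.update_rule == "vdam" and cfg.rho > 0:
            eligible = (n - last_sub) > cfg.substitution_cooldown
            bias_b = 1.0 - cfg.beta2 ** (n_updates + 1)
            sub = substitute_inactive_class(
                model.v1, model.v2, moments, running_mass, cfg.rho, eps_sub,
                ghat[0], ghat[1], fsc_vals, eta, eps2,
                cfg.beta1, cfg.beta2, eligible=eligible,
                bias2=float(bias_b.max()))
            if sub is not None:
                a, b = sub
                substituted = a
                last_sub[a] = n
                n_updates[a] = n_updates[b] + 1
                skip[a] = True   # a already carries b's one-step-ahead state
                skip[b] = True   # b keeps its previous references and moments

        if cfg.update_rule == "vmgd":
            for k in range(K):
                inv_tau2 = 0.0
                model.v1[k] = vmgd_update(model.v1[k],
                                          stats[0].f[k] * model.v1[k] - stats[0].b[k],
                                          stats[0].f[k], inv_tau2, eta)
                model.v2[k] = vmgd_update(model.v2[k],
                                          stats[1].f[k] * model.v2[k] - stats[1].b[k],
                                          stats[1].f[k], inv_tau2, eta)
        else:
            new_moments = update_moments(moments, ghat[0], ghat[1],
                                         cfg.beta1, cfg.beta2)
            for k in range(K):
                if skip[k]:
                    continue
                moments.m1[k] = new_moments.m1[k]
                moments.m2[k] = new_moments.m2[k]
                moments.u[k] = new_moments.u[k]
                n_updates[k] += 1
                bias2 = 1.0 - cfg.beta2 ** n_updates[k]
                model.v1[k] = vdam_update(model.v1[k], moments.m1[k],
                                          moments.u[k], curves[k], eta, eps2,
                                          bias2=bias2)
                model.v2[k] = vdam_update(model.v2[k], moments.m2[k],
                                          moments.u[k], curves[k], eta, eps2,
                                          bias2=bias2)
        # flush fully-damped coefficients to exact zero: the FSC shrinkage
        # drives inactive shells into subnormal magnitudes, which cost far
        # more CPU than they contribute (they are < 1e-20 of the signal)
        scale = max(np.abs(model.v1).max(), np.abs(model.v2).max(),
                    np.finfo(np.float64).tiny)
        floor = 1e-20 * scale
        for arr in (model.v1, model.v2, moments.m1, moments.m2):
            np.copyto(arr, 0, where=np.abs(arr) < floor)
        moments.u[moments.u < floor * floor] = 0.0
        if not np.all(np.isfinite(model.v1)) or not np.all(np.isfinite(model.v2)):
            raise FloatingPointError(
                f"non-finite reference values at batch {n}; "
                f"masses {running_mass}, eta {eta}")
        if cfg.keep_log:
            log_rows.append({"batch": n, "batchSize": bs, "eta": eta,
                             "evidence": evidence,
                             "substituted": -1 if substituted is None else substituted,
                             **{f"classMass{k + 1}": running_mass[k]
                                for k in range(K)}})
        model.fsc_curves = curves

    res = final_pass(xh, ch, model.combined, grid, model.sigma)
    model.class_probs = res["class_probs"]
    model.acc_rot, model.acc_trans = res["acc_rot"], res["acc_trans"]
    if model.fsc_curves:
        model.resolution = np.array([
            resolution_from_fsc(c, box, stack.pixel_size)
            for c in model.fsc_curves])
    else:
        model.resolution = np.full(K, 2.0 * stack.pixel_size)
    batch_log = pd.DataFrame(log_rows)
    return model, res["assignments"], batch_log
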