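"""Regularized likelihood core: per-pose likelihoods, posteriors over
(class, pose), sufficient statistics and the gradient.

Model
-----
Each particle's Fourier transform x is a transformed reference plus noise,

    x = H_q v_k + e,    e ~ CN(0, sigma),

with H_q = CTF . translation . rotation and sigma a diagonal, per-shell
noise covariance.  The log-likelihood of one particle given (k, q) is

    log P(x | v_k, q) = sum_f [ -|x_f - (H_q v_k)_f|^2 / sigma^2(s_f)
                                - log(pi sigma^2(s_f)) ]

summed over the full-grid Fourier coefficients inside the Nyquist disc
(Friedel mates counted twice — a uniform convention that cancels from all
posteriors).  Marginalizing q over a discrete pose grid with prior P(q)
and summing classes with uniform weights 1/K yields the per-particle
evidence; the sum of log-evidences is the data term of the objective.

The posterior-weighted accumulators are

    B_k = sum_i sum_q P_k(q|x_i) H_q^* (x_i / sigma^2)
    F_k = sum_i sum_q P_k(q|x_i) diag(H_q^* sigma^-2 H_q)

and the gradient of the regularized objective with respect to v_k
(Wirtinger derivative w.r.t. conj(v); the derivative w.r.t. the real /
imaginary parts is twice its real / imaginary part) is

    grad_k = B_k - (F_k + tau^-2) * v_k.

F_k keeps the diagonal of H^* sigma^-2 H in the standard gridding
convention: the CTF^2/sigma^2 weight image is scattered through the same
transposed interpolation weights as the data, which keeps the Wiener
ratio B/F unbiased under interpolation.  For rotations that are
multiples of 90 degrees the interpolation is an exact permutation and
F_k is exactly diag(H^* sigma^-2 H); the analytic identities (gradient
vs finite differences, EM monotonicity) hold exactly on such grids.

Hot-path layout: particles, CTFs and references are rfft2 half-planes
(box, box//2+1) in complex64/float32, with coefficients beyond Nyquist
zeroed.  Translation sums use separable phase matrices (two small complex
matmuls) rather than per-pose FFTs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import FourierGrid, fourier_grid
from .transform import PoseGrid, back_rotate_stack, rotate_fourier

__all__ = [
    "NoiseSpectrum", "SignalPrior", "PosteriorField", "SufficientStats",
    "log_likelihood", "pose_log_likelihoods", "compute_posteriors",
    "truncate_posteriors", "accumulate_stats", "gradient",
    "rotate_references", "residual_shell_power", "estimate_sigma",
]


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------

@dataclass
class NoiseSpectrum:
    """Per-shell noise variance sigma^2(s), strictly positive."""

    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.sigma2 = np.asarray(self.sigma2, dtype=np.float64)
        if np.any(self.sigma2 <= 0) or not np.all(np.isfinite(self.sigma2)):
            raise ValueError("noise variance must be finite and strictly positive")

    def __len__(self) -> int:
        return len(self.sigma2)


@dataclass
class SignalPrior:
    """Per-shell prior variance tau^2(s); +inf disables regularization."""

    tau2: np.ndarray

    def __post_init__(self) -> None:
        self.tau2 = np.asarray(self.tau2, dtype=np.float64)
        if np.any(self.tau2 <= 0):
            raise ValueError("signal prior variance must be positive")

    def inv(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            out = 1.0 / self.tau2
        return np.where(np.isinf(self.tau2), 0.0, out)


# --------------------------------------------------------------------------
# single-image reference implementation (full plane)
# --------------------------------------------------------------------------

def log_likelihood(x, v, pose, ctf, sigma: NoiseSpectrum) -> float:
    """log P(x | v, q) for one particle / reference pair (FourierImage in,
    scalar out).  Slow full-plane path used as ground truth in tests and
    for small problems."""
    from .transform import apply_transform

    g = fourier_grid(x.box)
    hv = apply_transform(v, pose, ctf)
    resid = x.coefficients - hv.coefficients
    s2 = np.asarray(sigma.sigma2)[g.shell_full]
    act = g.active_full
    quad = np.sum((np.abs(resid) ** 2 / s2)[act])
    norm = np.sum(np.log(np.pi * s2[act]))
    return float(-quad - norm)


# --------------------------------------------------------------------------
# hot path
# --------------------------------------------------------------------------

def _phase_matrices(grid: FourierGrid, pose_grid: PoseGrid):
    """Separable translation phase matrices for the half-plane layout.

    Returns (Ey, Ex, off_y, off_x): Ey[ky, j] = exp(-2 pi i ky ty_j / box)
    over the unique ty offsets, likewise Ex for tx; translations on the
    pose grid factor as an outer product of the two offset lists.
    """
    box = grid.box
    tx = np.unique(pose_grid.translations[:, 0])
    ty = np.unique(pose_grid.translations[:, 1])
    ky = np.fft.fftfreq(box, d=1.0 / box)
    kx = np.arange(box // 2 + 1, dtype=float)
    ey = np.exp(-2j * np.pi * ky[:, None] * ty[None, :] / box).astype(np.complex64)
    ex = np.exp(-2j * np.pi * kx[:, None] * tx[None, :] / box).astype(np.complex64)
    return ey, ex, ty, tx


def rotate_references(refs_half: np.ndarray, psis: np.ndarray, box: int,
                      dtype=np.complex64) -> np.ndarray:
    """Rotate K half-plane references by each grid angle (bilinear
    interpolation of the Fourier plane).

    Returns an array of shape (K, n_rot, box, box//2+1) in ``dtype``, with
    inactive (outside-Nyquist) coefficients zeroed.
    """
    g = fourier_grid(box)
    full = g.half_to_full(np.asarray(refs_half))
    cx = box // 2 + 1
    out = np.empty((full.shape[0], len(psis), box, cx), dtype)
    for j, psi in enumerate(psis):
        rot = rotate_fourier(full, float(psi))[..., :cx]
        rot[..., ~g.active_half] = 0.0
        out[:, j] = rot.astype(dtype)
    return out


def pose_log_likelihoods(x_half: np.ndarray, ctf_half: np.ndarray,
                         rot_refs: np.ndarray, pose_grid: PoseGrid,
                         sigma: NoiseSpectrum,
                         chunk: int = 256) -> np.ndarray:
    """log P(x_i | v_k, q) for every particle / class / grid pose.

    Parameters are half-plane arrays: ``x_half`` (B, box, box//2+1)
    complex64, ``ctf_half`` (B, box, box//2+1) float32, ``rot_refs``
    (K, n_rot, box, box//2+1) from :func:`rotate_references`.

    Returns (B, K, n_rot, n_trans); float32, or float64 when the particle
    coefficients come in as complex128 (the exact path used by tests of
    analytic identities).
    """
    B = x_half.shape[0]
    K, R, box, cx = rot_refs.shape
    double = x_half.dtype == np.complex128
    rdtype = np.float64 if double else np.float32
    cdtype = np.complex128 if double else np.complex64
    g = fourier_grid(box)
    s2 = np.asarray(sigma.sigma2, dtype=rdtype)
    w = np.where(g.active_half, 1.0 / s2[g.shell_half], 0.0).astype(rdtype)
    wm = (w * g.mult_half).astype(rdtype)
    ey, ex, ty, tx = _phase_matrices(g, pose_grid)
    ey = ey.astype(cdtype)
    ex = ex.astype(cdtype)
    nty, ntx = len(ty), len(tx)
    if nty * ntx != pose_grid.n_trans:
        raise ValueError("pose grid translations must form a separable grid")

    norm_const = -float(np.sum(g.mult_act * np.log(np.pi * s2[g.shell_act])))
    refs_flat = rot_refs.astype(cdtype).reshape(K * R, box, cx)
    ref_pow = np.abs(refs_flat.reshape(K * R, -1)) ** 2  # (KR, box*cx)
    e_full = np.einsum("yt,xu->yxtu", ey, ex).reshape(box * cx, nty * ntx)

    out = np.empty((B, K * R, nty, ntx), dtype=rdtype)
    s1 = np.empty(B, dtype=rdtype)
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        b = hi - lo
        xs = x_half[lo:hi]
        cs = ctf_half[lo:hi].astype(rdtype, copy=False)
        s1[lo:hi] = np.einsum("iyx,yx->i", np.abs(xs) ** 2, wm)
        wc2 = (wm[None] * cs * cs).reshape(b, -1)
        s2term = wc2 @ ref_pow.T                       # (b, KR)
        a = (wm[None] * cs) * np.conj(xs)              # (b, box, cx)
        # cross-correlation over all grid translations in one complex gemm
        gg = np.multiply(a[:, None, :, :], refs_flat[None, :, :, :])
        crs = (gg.reshape(-1, box * cx) @ e_full).reshape(b, K * R, nty, ntx)
        out[lo:hi] = (2.0 * crs.real
                      - s2term[:, :, None, None]
                      - s1[lo:hi, None, None, None])
    out += norm_const
    return out.reshape(B, K, R, nty * ntx)


def pose_log_likelihoods_pruned(x_half: np.ndarray, ctf_half: np.ndarray,
                                rot_refs: np.ndarray, pose_grid: PoseGrid,
                                sigma: NoiseSpectrum, keep_rot: int,
                                chunk: int = 256) -> np.ndarray:
    """Truncated-marginalization variant of :func:`pose_log_likelihoods`.

    Orientations with low probability are skipped from the marginalization:
    every (class, rotation) is first scored on a coarse translation subset
    (every other offset, centre included), then only the ``keep_rot`` best
    (class, rotation) pairs per particle are evaluated on the full
    translation grid.  Skipped entries are returned as -inf (zero posterior
    weight).
    """
    B = x_half.shape[0]
    K, R, box, cx = rot_refs.shape
    if keep_rot >= K * R:
        return pose_log_likelihoods(x_half, ctf_half, rot_refs, pose_grid,
                                    sigma, chunk=chunk)
    double = x_half.dtype == np.complex128
    rdtype = np.float64 if double else np.float32
    cdtype = np.complex128 if double else np.complex64
    g = fourier_grid(box)
    s2 = np.asarray(sigma.sigma2, dtype=rdtype)
    w = np.where(g.active_half, 1.0 / s2[g.shell_half], 0.0).astype(rdtype)
    wm = (w * g.mult_half).astype(rdtype)
    ey, ex, ty, tx = _phase_matrices(g, pose_grid)
    ey = ey.astype(cdtype)
    ex = ex.astype(cdtype)
    nty, ntx = len(ty), len(tx)
    norm_const = -float(np.sum(g.mult_act * np.log(np.pi * s2[g.shell_act])))
    refs_flat = rot_refs.astype(cdtype).reshape(K * R, box * cx)
    ref_pow = np.abs(refs_flat) ** 2
    e_full = np.einsum("yt,xu->yxtu", ey, ex).reshape(box * cx, nty * ntx)
    # coarse screen: a 3x3 grid of translations (centre and two-thirds of
    # the range along each axis)
    cy = np.unique(np.r_[-ty[-1] * 2 / 3, 0.0, ty[-1] * 2 / 3])
    cx_off = np.unique(np.r_[-tx[-1] * 2 / 3, 0.0, tx[-1] * 2 / 3])
    ky = np.fft.fftfreq(box, d=1.0 / box)
    kxi = np.arange(box // 2 + 1, dtype=float)
    eyc = np.exp(-2j * np.pi * ky[:, None] * cy[None, :] / box).astype(cdtype)
    exc = np.exp(-2j * np.pi * kxi[:, None] * cx_off[None, :] / box).astype(cdtype)
    e_coarse = np.einsum("yt,xu->yxtu", eyc, exc).reshape(box * cx, -1)

    out = np.full((B, K * R, nty * ntx), -np.inf, dtype=rdtype)
    refs_t = np.ascontiguousarray(refs_flat.reshape(K * R, -1).T)
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        b = hi - lo
        xs = x_half[lo:hi]
        cs = ctf_half[lo:hi].astype(rdtype, copy=False)
        s1 = np.einsum("iyx,yx->i", np.abs(xs) ** 2, wm)
        wc2 = (wm[None] * cs * cs).reshape(b, -1)
        s2term = wc2 @ ref_pow.T                        # (b, KR)
        a = ((wm[None] * cs) * np.conj(xs)).reshape(b, -1)
        # coarse screen: best cross term over the coarse translations,
        # one small gemm per coarse offset (no large intermediate)
        coarse = np.full((b, K * R), -np.inf, dtype=rdtype)
        for t in range(e_coarse.shape[1]):
            ct = ((a * e_coarse[:, t][None, :]) @ refs_t).real
            np.maximum(coarse, ct, out=coarse)
        coarse = 2.0 * coarse - s2term
        top = np.argpartition(-coarse, keep_rot - 1, axis=1)[:, :keep_rot]
        sel = (a[:, None, :]
               * refs_flat.reshape(K * R, -1)[top])     # (b, keep, box*cx)
        crs = (sel.reshape(-1, box * cx) @ e_full).reshape(b, keep_rot, -1)
        vals = (2.0 * crs.real
                - np.take_along_axis(s2term, top, axis=1)[:, :, None]
                - s1[:, None, None] + norm_const)
        for j in range(b):
            out[lo + j, top[j]] = vals[j]
    return out.reshape(B, K, R, nty * ntx)


@dataclass
class PosteriorField:
    """Normalized posterior weights over (class, rotation, translation)."""

    weights: np.ndarray       # (B, K, n_rot, n_trans), sums to 1 per particle
    log_evidence: np.ndarray  # (B,)

    @property
    def class_mass(self) -> np.ndarray:
        """Posterior probability mass per class, shape (K,)."""
        return self.weights.sum(axis=(0, 2, 3)).astype(np.float64)

    @property
    def per_particle_class(self) -> np.ndarray:
        """Per-particle class probabilities, shape (B, K)."""
        return self.weights.sum(axis=(2, 3)).astype(np.float64)


def compute_posteriors(log_lik: np.ndarray, pose_grid: PoseGrid,
                       class_weights: np.ndarray | None = None) -> PosteriorField:
    """Posterior P_k(q | x_i) from per-pose log-likelihoods.

    ``log_lik`` has shape (B, K, n_rot, n_trans).  Class weights default to
    uniform 1/K.  Stabilized with log-sum-exp; also returns the per-particle
    log-evidence log sum_k w_k sum_q P(x|k,q) P(q).
    """
    B, K, R, T = log_lik.shape
    if class_weights is None:
        class_weights = np.full(K, 1.0 / K)
    rdtype = log_lik.dtype
    class_weights = np.asarray(class_weights)
    log_prior = pose_grid.log_prior().reshape(1, 1, R, T)
    with np.errstate(divide="ignore"):
        logw = (log_lik + (log_prior
                + np.log(class_weights)[None, :, None, None]).astype(rdtype))
    flat = logw.reshape(B, -1)
    peak = flat.max(axis=1)
    shifted = np.exp(flat - peak[:, None])
    # flush sub-1e-30 weights to zero (subnormals are costly and carry no
    # posterior mass at this precision)
    np.copyto(shifted, 0, where=shifted < 1e-30)
    total = shifted.sum(axis=1, dtype=np.float64)
    log_ev = peak.astype(np.float64) + np.log(total)
    weights = (shifted / total[:, None].astype(rdtype)).reshape(B, K, R, T)
    norm_err = np.abs(weights.reshape(B, -1).sum(axis=1, dtype=np.float64) - 1.0)
    tol = 1e-12 if rdtype == np.float64 else 1e-5
    assert np.all(norm_err < tol), "posterior normalization failed"
    return PosteriorField(weights=weights, log_evidence=log_ev)


def truncate_posteriors(post: PosteriorField, mass_fraction: float) -> PosteriorField:
    """Keep, per particle, the smallest set of (k, q) entries whose
    cumulative weight reaches ``mass_fraction``; renormalize to 1."""
    if not 0.0 < mass_fraction <= 1.0:
        raise ValueError("mass_fraction must lie in (0, 1]")
    if mass_fraction == 1.0:
        return PosteriorField(post.weights.copy(), post.log_evidence.copy())
    B = post.weights.shape[0]
    flat = post.weights.reshape(B, -1)
    n = flat.shape[1]
    # fast path: the kept set is almost always within the top few hundred
    # entries; partial-sort those and fall back to a full sort otherwise
    top = min(1024, n)
    if top < n:
        part = np.argpartition(-flat, top - 1, axis=1)[:, :top]
        vals = np.take_along_axis(flat, part, axis=1)
        enough = vals.sum(axis=1, dtype=np.float64) >= mass_fraction
    else:
        part = np.broadcast_to(np.arange(n), flat.shape)
        vals = flat
        enough = np.ones(B, dtype=bool)
    order_in_part = np.argsort(-vals, axis=1, kind="stable")
    srt = np.take_along_axis(vals, order_in_part, axis=1)
    csum = np.cumsum(srt.astype(np.float64), axis=1)
    keep_sorted = (csum - srt) < mass_fraction
    out = np.zeros_like(flat)
    cols = np.take_along_axis(part, order_in_part, axis=1)
    np.put_along_axis(out, cols, np.where(keep_sorted, srt, 0.0), axis=1)
    if not enough.all():
        slow = np.flatnonzero(~enough)
        sub = flat[slow]
        order = np.argsort(-sub, axis=1, kind="stable")
        ssrt = np.take_along_axis(sub, order, axis=1)
        scs = np.cumsum(ssrt.astype(np.float64), axis=1)
        skeep = (scs - ssrt) < mass_fraction
        res = np.zeros_like(sub)
        np.put_along_axis(res, order, np.where(skeep, ssrt, 0.0), axis=1)
        out[slow] = res
    out /= out.sum(axis=1, keepdims=True)
    return PosteriorField(weights=out.reshape(post.weights.shape),
                          log_evidence=post.log_evidence.copy())


# --------------------------------------------------------------------------
# sufficient statistics
# --------------------------------------------------------------------------

@dataclass
class SufficientStats:
    """Per-class accumulators B_k, F_k and posterior class mass."""

    b: np.ndarray        # (K, box, box//2+1) complex128
    f: np.ndarray        # (K, box, box//2+1) float64, >= 0
    mass: np.ndarray     # (K,)
    n_particles: float

    @classmethod
    def zeros(cls, K: int, box: int) -> "SufficientStats":
        return cls(b=np.zeros((K, box, box // 2 + 1), np.complex128),
                   f=np.zeros((K, box, box // 2 + 1), np.float64),
                   mass=np.zeros(K), n_particles=0.0)

    def __iadd__(self, other: "SufficientStats") -> "SufficientStats":
        self.b += other.b
        self.f += other.f
        self.mass += other.mass
        self.n_particles += other.n_particles
        return self

    def scaled(self, c: float) -> "SufficientStats":
        return SufficientStats(self.b * c, self.f * c, self.mass * c,
                               self.n_particles * c)


def accumulate_stats(x_half: np.ndarray, ctf_half: np.ndarray,
                     post: PosteriorField, pose_grid: PoseGrid,
                     sigma: NoiseSpectrum, K: int | None = None) -> SufficientStats:
    """Accumulate B_k, F_k over a batch of particles.

    Entries of ``post.weights`` that are exactly zero (e.g. after
    truncation) are skipped.  Contributions are additive over particles.
    """
    B_n, Kp, R, T = post.weights.shape
    K = Kp if K is None else K
    box = x_half.shape[-2]
    cx = box // 2 + 1
    g = fourier_grid(box)
    s2 = np.asarray(sigma.sigma2, dtype=np.float64)
    w0 = np.where(g.active_half, 1.0 / s2[g.shell_half], 0.0)  # no multiplicity
    ey, ex, ty, tx = _phase_matrices(g, pose_grid)
    nty, ntx = len(ty), len(tx)

    cdtype = np.complex128 if x_half.dtype == np.complex128 else np.complex64
    p_rt = post.weights.sum(axis=3)                    # (B, K, R)
    keep = p_rt > 0.0
    xw = (x_half * (w0[None] * ctf_half)).astype(cdtype)   # ctf * x / sigma^2
    c2w = (w0[None] * ctf_half * ctf_half).reshape(B_n, -1)      # ctf^2 / sigma^2

    stats = SufficientStats.zeros(K, box)
    stats.mass = post.class_mass
    stats.n_particles = float(B_n)

    # F accumulation: per (k, r) weight sums, one sgemm
    p_kr = p_rt.reshape(B_n, K * R).astype(np.float64)
    f_acc = (p_kr.T @ c2w).reshape(K, R, box, cx)

    # B accumulation: translation-weighted data sums for every kept
    # (particle, class, rotation) triple at once, then a segment sum into
    # the per-(class, rotation) accumulators
    sel_i, sel_k, sel_r = np.nonzero(keep)
    conj_ey = np.conj(ey).astype(cdtype)
    conj_ex = np.conj(ex).astype(cdtype)
    b_acc = np.zeros((K * R, box * cx), np.complex128)
    if sel_i.size > 8 * B_n:
        # diffuse posteriors: sum over particles first (one weighted gemm
        # pair per translation), then apply the conjugate phase ramps
        xw_flat = xw.reshape(B_n, -1)
        e_all = np.einsum("yt,xu->yxtu", conj_ey, conj_ex).reshape(
            box * cx, nty * ntx)
        pw = post.weights.reshape(B_n, K * R, T)
        for t in range(T):
            pt = np.ascontiguousarray(pw[:, :, t]).astype(xw_flat.real.dtype)
            m_t = (pt.T @ xw_flat.real) + 1j * (pt.T @ xw_flat.imag)
            b_acc += m_t * e_all[:, t][None, :]
    elif sel_i.size:
        p = post.weights[sel_i, sel_k, sel_r].reshape(-1, nty, ntx)
        wmat = np.tensordot(p.astype(cdtype), conj_ex, axes=([2], [1]))
        wmat = np.tensordot(wmat, conj_ey, axes=([1], [1]))
        wmat = wmat.transpose(0, 2, 1)                   # (n, box, cx)
        contrib = (wmat * xw[sel_i]).reshape(sel_i.size, -1)
        group = sel_k * R + sel_r
        order = np.argsort(group, kind="stable")
        sorted_contrib = np.ascontiguousarray(contrib[order])
        sorted_group = group[order]
        bounds = np.flatnonzero(np.r_[True, np.diff(sorted_group) > 0])
        ends = np.r_[bounds[1:], sorted_group.size]
        for gidx, lo_, hi_ in zip(sorted_group[bounds], bounds, ends):
            b_acc[gidx] = sorted_contrib[lo_:hi_].sum(axis=0)
    b_acc = b_acc.reshape(K, R, box, cx)

    # back-rotate both accumulators, all grid angles in one sparse product
    b_k = back_rotate_stack(g.half_to_full(b_acc),
                            pose_grid.psis)[..., :cx]
    f_k = back_rotate_stack(g.half_to_full(f_acc), pose_grid.psis,
                            decenter=False)[..., :cx]
    stats.b = np.ascontiguousarray(b_k)
    stats.b[:, ~g.active_half] = 0.0
    stats.f = np.maximum(f_k, 0.0)
    stats.f[:, ~g.active_half] = 0.0
    return stats


def gradient(stats: SufficientStats, v_half: np.ndarray,
             tau: SignalPrior | None = None) -> np.ndarray:
    """grad_k = B_k - (F_k + tau^-2) * v_k (element-wise, per class).

    ``tau`` may be per-shell (broadcast onto the grid) or None (no
    regularization).  The negative of this quantity restricted to the data
    term is the G_k used by the gradient-descent optimizers.
    """
    v = np.asarray(v_half, dtype=np.complex128)
    box = v.shape[-2]
    g = fourier_grid(box)
    if tau is None:
        inv_tau2 = 0.0
    else:
        inv_tau2 = np.where(g.active_half, tau.inv()[..., g.shell_half], 0.0)
    return stats.b - (stats.f + inv_tau2) * v


# --------------------------------------------------------------------------
# noise estimation support
# --------------------------------------------------------------------------

def residual_shell_power(x_half: np.ndarray, ctf_half: np.ndarray,
                         rot_refs: np.ndarray, post: PosteriorField,
                         pose_grid: PoseGrid) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-weighted residual power per shell over a batch.

    Returns (power, counts): power[s] = sum over particles and coefficients
    in shell s (multiplicity-weighted) of E_post |x - H_q v|^2; counts[s] =
    number of contributing coefficients (times particles).
    """
    B_n, Kp, R, T = post.weights.shape
    K, _, box, cx = rot_refs.shape
    g = fourier_grid(box)
    cdtype = np.complex128 if x_half.dtype == np.complex128 else np.complex64
    ey, ex, ty, tx = _phase_matrices(g, pose_grid)
    ey = ey.astype(cdtype)
    ex = ex.astype(cdtype)
    nty, ntx = len(ty), len(tx)
    p_rt = post.weights.sum(axis=3)

    # E|x - Hv|^2 = |x|^2 - 2 Re[conj(x) sum_q P H v] + sum_q P |Hv|^2
    power = np.abs(x_half.astype(np.complex128)) ** 2  # (B, box, cx)
    refs_flat = rot_refs.reshape(K * R, box, cx)
    mean_hv = np.zeros((B_n, box, cx), np.complex128)
    for k in range(K):
        for r in range(R):
            sel = np.flatnonzero(p_rt[:, k, r] > 0)
            if not sel.size:
                continue
            p = post.weights[sel, k, r].reshape(sel.size, nty, ntx)
            wmat = np.tensordot(p.astype(cdtype), ex, axes=([2], [1]))
            wmat = np.tensordot(wmat, ey, axes=([1], [1])).transpose(0, 2, 1)
            mean_hv[sel] += wmat * (ctf_half[sel] * refs_flat[k * R + r][None])
    power -= 2.0 * np.real(np.conj(x_half) * mean_hv)
    p_kr = p_rt.reshape(B_n, K * R).astype(np.float64)
    ref_pow = np.abs(refs_flat) ** 2
    power += np.einsum("ik,kyx,iyx->iyx", p_kr, ref_pow,
                       (ctf_half * ctf_half).astype(np.float64))
    power = np.maximum(power, 0.0)
    shell_power = g.shell_sum(g.pack(power.sum(axis=0)))
    counts = g.shell_counts * B_n
    return shell_power, counts


def estimate_sigma(shell_power: np.ndarray, counts: np.ndarray,
                   floor: float = 1e-10) -> NoiseSpectrum:
    """sigma^2(s) = residual power / coefficient count, floored."""
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError("shell counts must be positive")
    s2 = np.asarray(shell_power, dtype=np.float64) / counts
    ref = s2[s2 > 0].mean() if np.any(s2 > 0) else 1.0
    return NoiseSpectrum(np.maximum(s2, max(floor, 1e-12 * ref)))
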