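"""Shared machinery for the EM and VDAM optimizers: half-set E-steps,
the final assignment pass and per-class alignment-accuracy summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import fourier_grid
from .likelihood import (NoiseSpectrum, PosteriorField, compute_posteriors,
                         pose_log_likelihoods, pose_log_likelihoods_pruned,
                         rotate_references)
from .transform import PoseGrid

__all__ = ["half_indices", "estep", "final_pass", "data_power_sigma",
           "prior_objective"]


def half_indices(halfset: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.flatnonzero(halfset == 1), np.flatnonzero(halfset == 2)


def estep(x_half: np.ndarray, ctf_half: np.ndarray, refs_half: np.ndarray,
          pose_grid: PoseGrid, sigma: NoiseSpectrum,
          class_weights: np.ndarray | None = None,
          rot_refs: np.ndarray | None = None,
          keep_rot: int | None = None) -> tuple[PosteriorField, np.ndarray]:
    """Posteriors of a particle subset against one set of references.

    ``keep_rot`` enables truncated marginalization: only that many
    (class, rotation) pairs per particle (preselected on a coarse
    translation screen) enter the integral; the rest get zero weight.
    """
    box = x_half.shape[-2]
    dtype = np.complex128 if x_half.dtype == np.complex128 else np.complex64
    if rot_refs is None:
        rot_refs = rotate_references(refs_half, pose_grid.psis, box, dtype=dtype)
    if keep_rot is None:
        ll = pose_log_likelihoods(x_half, ctf_half, rot_refs, pose_grid, sigma)
    else:
        ll = pose_log_likelihoods_pruned(x_half, ctf_half, rot_refs,
                                         pose_grid, sigma, keep_rot)
    return compute_posteriors(ll, pose_grid, class_weights), rot_refs


def data_power_sigma(x_half: np.ndarray) -> NoiseSpectrum:
    """Initial noise spectrum: per-shell mean power of the data (an
    overestimate, since it includes signal)."""
    box = x_half.shape[-2]
    g = fourier_grid(box)
    power = g.shell_sum(g.pack(np.abs(x_half) ** 2).mean(axis=0).astype(np.float64))
    return NoiseSpectrum(np.maximum(power / g.shell_counts, 1e-10))


def prior_objective(v_half: np.ndarray, tau2: np.ndarray) -> float:
    """Gaussian prior term sum_k sum_f [-|v|^2/tau^2 - log(pi tau^2)] over
    full-grid coefficients (multiplicity-weighted half-plane sum)."""
    box = v_half.shape[-2]
    g = fourier_grid(box)
    total = 0.0
    for k in range(v_half.shape[0]):
        t2 = np.asarray(tau2[k])[g.shell_act]
        vv = np.abs(g.pack(v_half[k])) ** 2
        total += float(np.sum(g.mult_act * (-vv / t2 - np.log(np.pi * t2))))
    return total


def _pose_spread(post: PosteriorField, pose_grid: PoseGrid) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-weighted per-class spreads of rotation (deg) and
    translation (px) around each particle's best pose."""
    B, K, R, T = post.weights.shape
    psis = np.asarray(pose_grid.psis)
    trans = np.asarray(pose_grid.translations)
    flat = post.weights.reshape(B, K, R * T)
    best = flat.reshape(B, -1).argmax(axis=1)
    best_k = best // (R * T)
    best_r = (best % (R * T)) // T
    best_t = best % T
    dpsi = np.abs(psis[None, :] - psis[best_r][:, None])
    dpsi = np.minimum(dpsi, 360.0 - dpsi)                       # (B, R)
    dtr = np.linalg.norm(trans[None, :, :] - trans[best_t][:, None, :], axis=2)
    w_rt = post.weights.sum(axis=1)                              # (B, R, T)
    wsum = np.maximum(w_rt.sum(axis=(1, 2)), 1e-12)
    rot_var = (w_rt.sum(axis=2) * dpsi ** 2).sum(axis=1) / wsum
    tr_var = (w_rt.sum(axis=1) * dtr ** 2).sum(axis=1) / wsum
    acc_rot = np.zeros(K)
    acc_tr = np.zeros(K)
    for k in range(K):
        sel = best_k == k
        if sel.any():
            acc_rot[k] = np.sqrt(rot_var[sel].mean())
            acc_tr[k] = np.sqrt(tr_var[sel].mean())
    return acc_rot, acc_tr


def final_pass(x_half: np.ndarray, ctf_half: np.ndarray, refs_half: np.ndarray,
               pose_grid: PoseGrid, sigma: NoiseSpectrum,
               chunk: int = 512) -> dict:
    """Full pass computing only class probabilities and assignments.

    Uses the combined references; returns P(X|k), per-particle class
    numbers (1-based), best poses, per-particle max class probability and
    per-class alignment-accuracy estimates.
    """
    N = x_half.shape[0]
    box = x_half.shape[-2]
    K = refs_half.shape[0]
    rot_refs = rotate_references(refs_half, pose_grid.psis, box)
    class_mass = np.zeros(K)
    rows = []
    acc_rot_acc = np.zeros(K)
    acc_tr_acc = np.zeros(K)
    acc_n = np.zeros(K)
    log_ev = np.empty(N)
    for lo in range(0, N, chunk):
        hi = min(lo + chunk, N)
        post, _ = estep(x_half[lo:hi], ctf_half[lo:hi], refs_half, pose_grid,
                        sigma, rot_refs=rot_refs)
        log_ev[lo:hi] = post.log_evidence
        pk = post.per_particle_class                       # (b, K)
        class_mass += pk.sum(axis=0)
        best_k = pk.argmax(axis=1)
        flat = post.weights.reshape(hi - lo, K, -1)
        T = pose_grid.n_trans
        best_q = np.array([flat[i, best_k[i]].argmax() for i in range(hi - lo)])
        psis = pose_grid.psis[best_q // T]
        ts = pose_grid.translations[best_q % T]
        for i in range(hi - lo):
            rows.append((int(best_k[i]) + 1, float(pk[i, best_k[i]]),
                         float(psis[i]), float(ts[i, 0]), float(ts[i, 1])))
        a_r, a_t = _pose_spread(post, pose_grid)
        counts = np.bincount(best_k, minlength=K)
        acc_rot_acc += a_r * counts
        acc_tr_acc += a_t * counts
        acc_n += counts
    assignments = pd.DataFrame(rows, columns=[
        "rlnClassNumber", "rlnMaxValueProbDistribution",
        "rlnAnglePsi", "rlnOriginX", "rlnOriginY"])
    nz = acc_n > 0
    acc_rot = np.where(nz, acc_rot_acc / np.maximum(acc_n, 1), 0.0)
    acc_tr = np.where(nz, acc_tr_acc / np.maximum(acc_n, 1), 0.0)
    return {"class_probs": class_mass / class_mass.sum(),
            "assignments": assignments,
            "acc_rot": acc_rot, "acc_trans": acc_tr,
            "log_evidence": log_ev}
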