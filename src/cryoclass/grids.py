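"""Frequency grids, resolution shells and FFT conventions.

All image <-> Fourier transforms in this package use orthonormal FFTs
(``norm="ortho"``), so Parseval's identity holds without extra factors and
the adjoint of the FFT is its inverse.

Real images are carried as rfft2 half-planes of shape (box, box//2 + 1);
scalar reductions over "the full grid" are recovered with a per-coefficient
multiplicity weight (2 for columns strictly inside the half-plane, whose
Friedel mates live in the discarded half, 1 for the kx = 0 and kx = Nyquist
columns which already contain their own mates).

The model operates on coefficients strictly inside the Nyquist disc
(integer shell radius < box/2): the Nyquist ring itself is excluded, both
because it is aliased (its +/- frequency pairs coincide on the grid, which
makes an astigmatic CTF ambiguous there) and because corner coefficients
beyond it carry no isotropic shell.  Excluded coefficients take no part in
likelihood sums, noise/FSC shells or reference updates.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.fft as sfft

__all__ = [
    "FourierGrid", "fourier_grid", "fft_image", "ifft_image",
    "rfft_image", "irfft_image",
]


class FourierGrid:
    """Precomputed index machinery for a box x box Fourier grid."""

    def __init__(self, box: int):
        if box < 4 or box % 2:
            raise ValueError(f"box must be even and >= 4, got {box}")
        self.box = box
        self.n_shells = box // 2           # shells 0 .. box//2 - 1
        # half-plane (rfft2) integer frequency coordinates
        ky = np.fft.fftfreq(box, d=1.0 / box)          # (box,)
        kx = np.arange(box // 2 + 1, dtype=float)      # (box//2+1,)
        self.ky_half = ky[:, None] + 0.0 * kx[None, :]
        self.kx_half = 0.0 * ky[:, None] + kx[None, :]
        r_half = np.hypot(self.ky_half, self.kx_half)
        self.shell_half = np.rint(r_half).astype(np.int32)
        self.active_half = self.shell_half < box // 2
        self.shell_half = np.minimum(self.shell_half, box // 2 - 1)
        mult = np.full((box, box // 2 + 1), 2.0)
        mult[:, 0] = 1.0
        mult[:, -1] = 1.0
        self.mult_half = np.where(self.active_half, mult, 0.0)
        # full-plane coordinates (standard fft2 layout)
        kyf = ky[:, None] + 0.0 * ky[None, :]
        kxf = 0.0 * ky[:, None] + ky[None, :]
        self.ky_full, self.kx_full = kyf, kxf
        r_full = np.hypot(kyf, kxf)
        self.shell_full = np.minimum(np.rint(r_full).astype(np.int32),
                                     box // 2 - 1)
        self.active_full = np.rint(r_full) < box // 2
        # packed active half-plane coefficients (hot-path layout)
        self.act_idx = np.flatnonzero(self.active_half.ravel())
        self.n_active = self.act_idx.size
        self.mult_act = self.mult_half.ravel()[self.act_idx]
        self.shell_act = self.shell_half.ravel()[self.act_idx]
        self.ky_act = self.ky_half.ravel()[self.act_idx]
        self.kx_act = self.kx_half.ravel()[self.act_idx]
        self.shell_counts = np.bincount(
            self.shell_act, weights=self.mult_act, minlength=self.n_shells)

    # ---- packing helpers -------------------------------------------------
    def pack(self, half: np.ndarray) -> np.ndarray:
        """Extract active coefficients from (..., box, box//2+1) arrays."""
        return half.reshape(*half.shape[:-2], -1)[..., self.act_idx]

    def unpack(self, packed: np.ndarray) -> np.ndarray:
        """Scatter packed coefficients back onto a zero-filled half-plane."""
        out = np.zeros((*packed.shape[:-1], self.box * (self.box // 2 + 1)),
                       dtype=packed.dtype)
        out[..., self.act_idx] = packed
        return out.reshape(*packed.shape[:-1], self.box, self.box // 2 + 1)

    # ---- shell reductions ------------------------------------------------
    def shell_sum(self, packed_vals: np.ndarray) -> np.ndarray:
        """Multiplicity-weighted per-shell sum of packed real values."""
        return np.bincount(self.shell_act, weights=self.mult_act * packed_vals,
                           minlength=self.n_shells)

    def shell_mean(self, packed_vals: np.ndarray) -> np.ndarray:
        return self.shell_sum(packed_vals) / self.shell_counts

    def expand_shells(self, per_shell: np.ndarray) -> np.ndarray:
        """Broadcast per-shell values onto the packed coefficient layout."""
        return np.asarray(per_shell)[..., self.shell_act]

    def freq_in_inv_angstrom(self, pixel_size: float):
        """Packed (fy, fx) spatial frequencies in 1/Angstrom."""
        scale = 1.0 / (self.box * pixel_size)
        return self.ky_act * scale, self.kx_act * scale

    def half_to_full(self, half: np.ndarray) -> np.ndarray:
        """Expand a Hermitian half-plane (rfft2 layout) to the full fft2
        grid using Friedel symmetry (complex conjugation; for real-valued
        even images this is a plain mirror)."""
        box = self.box
        cx = box // 2 + 1
        full = np.zeros((*half.shape[:-2], box, box), dtype=half.dtype)
        full[..., :cx] = half
        ky = (-np.arange(box)) % box
        src = half[..., ky, 1:box // 2]
        if np.iscomplexobj(half):
            src = np.conj(src)
        full[..., :, box - 1:box // 2:-1] = src
        return full


@lru_cache(maxsize=32)
def fourier_grid(box: int) -> FourierGrid:
    return FourierGrid(box)


# ---- orthonormal FFT wrappers -------------------------------------------

def fft_image(img: np.ndarray) -> np.ndarray:
    """Full-plane orthonormal 2D FFT over the last two axes."""
    return sfft.fft2(img, axes=(-2, -1), norm="ortho")


def ifft_image(coeffs: np.ndarray) -> np.ndarray:
    return sfft.ifft2(coeffs, axes=(-2, -1), norm="ortho")


def rfft_image(img: np.ndarray) -> np.ndarray:
    """Half-plane orthonormal 2D FFT of a real image."""
    return sfft.rfft2(img, axes=(-2, -1), norm="ortho")


def irfft_image(half: np.ndarray, box: int) -> np.ndarray:
    return sfft.irfft2(half, s=(box, box), axes=(-2, -1), norm="ortho")
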