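"""The forward operator H_q: in-plane rotation + translation + CTF.

Conventions
-----------
* Rotation acts on the Fourier coefficients directly: each output
  coefficient pulls, with bilinear weights, from the reference's Fourier
  plane at the back-rotated frequency coordinate (the 2D analogue of
  Fourier-slice extraction).  Each rotation is a sparse linear map S(psi)
  on the centred (fftshifted) grid; the adjoint used in back-projection is
  the exact matrix transpose.  For angles that are multiples of 90 degrees
  S is an exact permutation.  The CTF^2/sigma^2 weight accumulation used
  for the diagonal F_k scatters the weight image with the same transposed
  interpolation weights (the standard gridding convention, which keeps the
  Wiener ratio B/F unbiased; it equals the exact diagonal of
  H* sigma^-2 H whenever S is a permutation).
* Translation by t pixels multiplies Fourier coefficient k by
  exp(-2*pi*i*(k . t)/box).
* The CTF multiplies element-wise in Fourier space.

The same sparse maps applied to real-space images provide plain bilinear
image rotation (used for fixtures and display).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .grids import fft_image, ifft_image

__all__ = [
    "FourierImage", "Pose", "PoseGrid", "make_pose_grid",
    "rotation_matrix", "rotate_real",
    "rotate_fourier", "apply_transform", "adjoint_transform",
    "phase_ramp_full",
]


# --------------------------------------------------------------------------
# rotation operators
# --------------------------------------------------------------------------

def _bilinear_entries(box: int, psi_deg: float):
    c = box // 2
    jj, ii = np.meshgrid(np.arange(box), np.arange(box))  # ii: row, jj: col
    th = np.deg2rad(psi_deg)
    cos, sin = np.cos(th), np.sin(th)
    # source coordinates: rotate output coords by -psi about the centre
    dy = ii - c
    dx = jj - c
    sy = c + cos * dy + sin * dx
    sx = c - sin * dy + cos * dx
    y0 = np.floor(sy).astype(np.int64)
    x0 = np.floor(sx).astype(np.int64)
    fy = sy - y0
    fx = sx - x0
    rows = (ii * box + jj).ravel()
    data, cols_idx, rows_idx = [], [], []
    for oy, ox, w in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        cols = ((y0 + oy) % box) * box + ((x0 + ox) % box)
        rows_idx.append(rows)
        cols_idx.append(cols.ravel())
        data.append(w.ravel())
    return (np.concatenate(rows_idx), np.concatenate(cols_idx),
            np.concatenate(data))


def _assemble(box: int, rows, cols, data) -> sp.csr_matrix:
    mat = sp.coo_matrix((data, (rows, cols)), shape=(box * box, box * box))
    mat.sum_duplicates()
    mat.data[np.abs(mat.data) < 1e-12] = 0.0
    mat.eliminate_zeros()
    return mat.tocsr()


@lru_cache(maxsize=512)
def rotation_matrix(box: int, psi_deg: float) -> sp.csr_matrix:
    """Sparse (box^2 x box^2) bilinear rotation by ``psi_deg`` (CCW) about
    the grid centre (box//2, box//2), with periodic wrap."""
    return _assemble(box, *_bilinear_entries(box, psi_deg))


def rotate_real(img: np.ndarray, psi_deg: float, adjoint: bool = False) -> np.ndarray:
    """Rotate a (possibly complex) image array by bilinear interpolation;
    ``adjoint`` applies the exact transpose map."""
    box = img.shape[-1]
    mat = rotation_matrix(box, float(psi_deg) % 360.0)
    if adjoint:
        mat = mat.T
    flat = img.reshape(-1, box * box)
    out = (mat @ flat.T).T
    return np.ascontiguousarray(out.reshape(img.shape))


@lru_cache(maxsize=8)
def _checkerboard(box: int) -> np.ndarray:
    i = np.arange(box)
    return ((-1.0) ** (i[:, None] + i[None, :]))


@lru_cache(maxsize=32)
def _block_adjoint_matrix(box: int, psis: tuple) -> sp.csr_matrix:
    """Block-diagonal stack of transposed rotation matrices, one block per
    grid angle — applies every back-rotation in a single sparse product."""
    return sp.block_diag([rotation_matrix(box, float(p) % 360.0).T
                          for p in psis], format="csr")


def back_rotate_stack(coeffs_full: np.ndarray, psis, decenter: bool = True) -> np.ndarray:
    """Sum of back-rotations over grid angles.

    ``coeffs_full`` has shape (..., n_rot, box, box) (fft2 layout, one
    plane per angle); returns sum_r S(psi_r)^T applied to plane r, shape
    (..., box, box).  Equivalent to looping :func:`rotate_fourier` with
    ``adjoint=True`` and summing, but with one sparse product.
    """
    box = coeffs_full.shape[-1]
    R = coeffs_full.shape[-2 - 1]
    mat = _block_adjoint_matrix(box, tuple(float(p) for p in psis))
    shifted = np.fft.fftshift(coeffs_full, axes=(-2, -1))
    if decenter:
        shifted = shifted * _checkerboard(box)
    flat = shifted.reshape(-1, R * box * box)
    out = (mat @ flat.T).T.reshape(*coeffs_full.shape[:-3], R, box, box)
    out = out.sum(axis=-3)
    if decenter:
        out = out * _checkerboard(box)
    return np.ascontiguousarray(np.fft.ifftshift(out, axes=(-2, -1)))


def rotate_fourier(coeffs_full: np.ndarray, psi_deg: float,
                   adjoint: bool = False, decenter: bool = True) -> np.ndarray:
    """Rotate full-plane Fourier coefficients (fft2 layout) by bilinear
    interpolation on the centred frequency grid.

    The spectrum of an object centred at (box//2, box//2) oscillates with
    a (+1, -1) checkerboard phase; interpolation is therefore performed on
    the de-centred spectrum (checkerboard removed, restored afterwards),
    where the transform of a compact object is smooth.  ``adjoint``
    applies the exact transpose (back-projection).  ``decenter=False``
    skips the checkerboard (used when rotating plain weight images rather
    than spectra of centred objects).
    """
    box = coeffs_full.shape[-1]
    mat = rotation_matrix(box, float(psi_deg) % 360.0)
    if adjoint:
        mat = mat.T
    shifted = np.fft.fftshift(coeffs_full, axes=(-2, -1))
    if decenter:
        shifted = shifted * _checkerboard(box)
    flat = shifted.reshape(-1, box * box)
    out = (mat @ flat.T).T.reshape(shifted.shape)
    if decenter:
        out = out * _checkerboard(box)
    return np.ascontiguousarray(np.fft.ifftshift(out, axes=(-2, -1)))


# --------------------------------------------------------------------------
# poses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Pose:
    """In-plane pose: rotation psi in degrees, translation in pixels."""

    psi: float
    tx: float = 0.0
    ty: float = 0.0


@dataclass
class PoseGrid:
    """Discrete transformation set Q with prior weights P(q).

    The grid is the Cartesian product of ``psis`` (uniform prior) and
    ``translations`` (2D Gaussian prior), with the joint prior normalized to
    sum to one over the grid.
    """

    psis: np.ndarray                 # (n_rot,) degrees
    translations: np.ndarray         # (n_trans, 2) pixels, columns (tx, ty)
    trans_prior: np.ndarray          # (n_trans,) sums to 1
    translation_sigma: float = field(default=2.0)

    @property
    def n_rot(self) -> int:
        return len(self.psis)

    @property
    def n_trans(self) -> int:
        return len(self.translations)

    @property
    def n_poses(self) -> int:
        return self.n_rot * self.n_trans

    @property
    def prior(self) -> np.ndarray:
        """Flattened joint prior over (rotation, translation), sums to 1."""
        return (np.full(self.n_rot, 1.0 / self.n_rot)[:, None]
                * self.trans_prior[None, :]).ravel()

    @property
    def poses(self) -> list[Pose]:
        return [Pose(psi=float(p), tx=float(t[0]), ty=float(t[1]))
                for p in self.psis for t in self.translations]

    def log_prior(self) -> np.ndarray:
        """Log joint prior, shape (n_rot, n_trans)."""
        with np.errstate(divide="ignore"):
            row = np.log(self.trans_prior) - np.log(self.n_rot)
        return np.broadcast_to(row[None, :], (self.n_rot, self.n_trans)).copy()


def make_pose_grid(angular_step: float, max_translation: int,
                   translation_step: int = 1, translation_sigma: float = 2.0,
                   box: int | None = None) -> PoseGrid:
    """Build the pose grid Q with its prior P(q).

    ``angular_step`` (degrees) must divide 360; translations span the square
    [-max_translation, max_translation]^2 at ``translation_step`` pixels with
    an isotropic Gaussian prior of width ``translation_sigma`` (pixels;
    ``inf`` gives a uniform translation prior).
    """
    n_rot = 360.0 / angular_step
    if abs(n_rot - round(n_rot)) > 1e-9:
        raise ValueError(f"angular_step {angular_step} does not divide 360")
    if box is not None and max_translation >= box / 2:
        raise ValueError(
            f"max_translation {max_translation} must be < box/2 = {box / 2}")
    psis = np.arange(int(round(n_rot))) * float(angular_step)
    offs = np.arange(-max_translation, max_translation + 1, translation_step)
    tx, ty = np.meshgrid(offs, offs)
    translations = np.stack([tx.ravel(), ty.ravel()], axis=1).astype(np.float64)
    r2 = (translations ** 2).sum(axis=1)
    if np.isinf(translation_sigma):
        w = np.ones(len(translations))
    else:
        w = np.exp(-r2 / (2.0 * translation_sigma ** 2))
    return PoseGrid(psis=psis, translations=translations,
                    trans_prior=w / w.sum(),
                    translation_sigma=float(translation_sigma))


# --------------------------------------------------------------------------
# full-plane reference implementation of H_q
# --------------------------------------------------------------------------

@dataclass
class FourierImage:
    """Complex Fourier coefficients on a box x box grid (fft2 layout)."""

    coefficients: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.complex128)
        if (self.coefficients.ndim != 2
                or self.coefficients.shape[0] != self.coefficients.shape[1]):
            raise ValueError("FourierImage must be square")

    @classmethod
    def from_real(cls, img: np.ndarray, pixel_size: float = 1.0) -> "FourierImage":
        return cls(fft_image(np.asarray(img, dtype=np.float64)), pixel_size)

    def to_real(self) -> np.ndarray:
        return ifft_image(self.coefficients).real

    @property
    def box(self) -> int:
        return self.coefficients.shape[0]


def phase_ramp_full(box: int, tx: float, ty: float) -> np.ndarray:
    """exp(-2 pi i (k . t) / box) on the full fft2 grid."""
    k = np.fft.fftfreq(box, d=1.0 / box)
    return np.exp(-2j * np.pi * (k[:, None] * ty + k[None, :] * tx) / box)


def apply_transform(v: FourierImage, pose: Pose,
                    ctf: np.ndarray | float = 1.0) -> FourierImage:
    """H_q v: rotate (Fourier interpolation), translate (phase ramp), then
    CTF-multiply."""
    box = v.box
    rotated = rotate_fourier(v.coefficients, pose.psi)
    ramp = phase_ramp_full(box, pose.tx, pose.ty)
    return FourierImage(rotated * ramp * ctf, v.pixel_size)


def adjoint_transform(x: FourierImage, pose: Pose,
                      ctf: np.ndarray | float = 1.0) -> FourierImage:
    """H_q^* x: the exact adjoint of :func:`apply_transform`."""
    box = x.box
    ramp = phase_ramp_full(box, pose.tx, pose.ty)
    back = x.coefficients * np.conj(ramp) * np.conj(ctf)
    return FourierImage(rotate_fourier(back, pose.psi, adjoint=True),
                        x.pixel_size)
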