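"""Class model state shared by the optimizers: half-set references, FSC
curves, noise / signal spectra and derived per-class quantities.

Half sets: particles with odd / even parity are refined against separate
references v_{k,h1}, v_{k,h2}; their Fourier shell correlation (FSC) per
class estimates the signal-to-noise of the current reference without
circularity, and drives both the signal prior tau^2 (via
SNR = FSC / (1 - FSC)) and the VDAM update damping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import fourier_grid, irfft_image, rfft_image
from .likelihood import NoiseSpectrum, SignalPrior
from .mrc import ImageStack
from .star import MetadataTable

__all__ = ["FscCurve", "ClassModel", "fsc", "estimate_tau",
           "resolution_from_fsc", "init_gaussian_blobs"]

FSC_CLIP = 0.999   # avoid infinite SNR at FSC -> 1
TAU2_FLOOR = 1e-10


@dataclass
class FscCurve:
    """Per-shell correlation values in [-1, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(np.abs(self.values) > 1.0 + 1e-9):
            raise ValueError("FSC values must lie in [-1, 1]")
        self.values = np.clip(self.values, -1.0, 1.0)


def fsc(a_half: np.ndarray, b_half: np.ndarray, min_coeffs: int = 1) -> FscCurve:
    """Fourier shell correlation between two half-plane Fourier images.

    Per shell s:  Re sum a conj(b) / sqrt(sum |a|^2 sum |b|^2), with
    multiplicity weights so Friedel mates count as on the full grid.
    Shells with zero power on either side give 0; shells with fewer than
    ``min_coeffs`` coefficients inherit the previous shell's value.
    """
    box = a_half.shape[-2]
    g = fourier_grid(box)
    pa = g.pack(np.asarray(a_half))
    pb = g.pack(np.asarray(b_half))
    num = g.shell_sum(np.real(pa * np.conj(pb)))
    pow_a = g.shell_sum(np.abs(pa) ** 2)
    pow_b = g.shell_sum(np.abs(pb) ** 2)
    denom = np.sqrt(pow_a * pow_b)
    vals = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    if min_coeffs > 1:
        for s in range(1, len(vals)):
            if g.shell_counts[s] < min_coeffs:
                vals[s] = vals[s - 1]
    return FscCurve(np.clip(vals, -1.0, 1.0))


def estimate_tau(curve: FscCurve, f_half: np.ndarray) -> SignalPrior:
    """Signal prior tau^2(s) from a half-set FSC and the weight image F.

    SNR(s) = FSC / (1 - FSC) (FSC clipped to [0, 0.999]); tau^2 = SNR
    divided by the per-shell mean of F, floored at a small positive
    constant.  The per-shell form of the underlying SSNR relation is a
    documented convention (see docs/methods.md).
    """
    box = f_half.shape[-2]
    g = fourier_grid(box)
    c = np.clip(curve.values, 0.0, FSC_CLIP)
    snr = c / (1.0 - c)
    mean_f = np.maximum(g.shell_mean(g.pack(np.asarray(f_half))), 1e-30)
    return SignalPrior(np.maximum(snr / mean_f, TAU2_FLOOR))


def resolution_from_fsc(curve: FscCurve, box: int, pixel_size: float,
                        threshold: float = 0.5) -> float:
    """Estimated resolution d in Angstrom: first shell where FSC drops
    below ``threshold`` (Nyquist, 2 * pixel_size, if it never does)."""
    vals = curve.values
    for s in range(1, len(vals)):
        if vals[s] < threshold:
            return box * pixel_size / s
    return 2.0 * pixel_size


def init_gaussian_blobs(K: int, box: int, seed: int = 0,
                        amplitude: float = 1.0) -> np.ndarray:
    """Randomly positioned Gaussian blobs, one per class.

    Centres are drawn uniformly within the inner half of the box, widths
    uniformly in [box/12, box/7] pixels; deterministic for a fixed seed and
    pairwise distinct for K <= 100.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    jj, ii = np.meshgrid(np.arange(box), np.arange(box))
    c = box // 2
    out = np.empty((K, box, box))
    for k in range(K):
        cy, cx_ = rng.uniform(-box / 4.0, box / 4.0, size=2)
        width = rng.uniform(box / 12.0, box / 7.0)
        out[k] = amplitude * np.exp(-((ii - c - cy) ** 2 + (jj - c - cx_) ** 2)
                                    / (2.0 * width ** 2))
    return out


@dataclass
class ClassModel:
    """K class references as two half-set Fourier images plus spectra.

    References are rfft2 half-planes (K, box, box//2+1); ``combined`` is
    the average of the two halves and is what gets written out as the
    class averages.
    """

    v1: np.ndarray
    v2: np.ndarray
    pixel_size: float
    sigma: NoiseSpectrum
    class_probs: np.ndarray
    fsc_curves: list[FscCurve] = field(default_factory=list)
    tau2: np.ndarray | None = None            # (K, n_shells) or None
    resolution: np.ndarray | None = None      # (K,) Angstrom
    acc_rot: np.ndarray | None = None         # (K,) degrees
    acc_trans: np.ndarray | None = None       # (K,) pixels

    @property
    def n_classes(self) -> int:
        return self.v1.shape[0]

    @property
    def box(self) -> int:
        return self.v1.shape[-2]

    @property
    def combined(self) -> np.ndarray:
        return 0.5 * (self.v1 + self.v2)

    def class_averages(self) -> np.ndarray:
        """Real-space class average images, (K, box, box)."""
        return irfft_image(self.combined, self.box).real

    @classmethod
    def from_real_references(cls, refs: np.ndarray, pixel_size: float,
                             sigma: NoiseSpectrum) -> "ClassModel":
        g = fourier_grid(refs.shape[-1])
        v = rfft_image(np.asarray(refs, dtype=np.float64))
        v[:, ~g.active_half] = 0.0
        K = refs.shape[0]
        return cls(v1=v.copy(), v2=v.copy(), pixel_size=pixel_size,
                   sigma=sigma, class_probs=np.full(K, 1.0 / K))

    def to_tables(self) -> MetadataTable:
        """Model summary STAR table (one row per class)."""
        K = self.n_classes
        df = pd.DataFrame({
            "rlnReferenceImage": [f"{k + 1:03d}" for k in range(K)],
            "rlnClassPriorOffset": np.zeros(K),
            "rlnClassDistribution": np.asarray(self.class_probs, dtype=float),
            "rlnEstimatedResolution": (self.resolution if self.resolution
                                       is not None else np.zeros(K)),
            "rlnAccuracyRotations": (self.acc_rot if self.acc_rot is not None
                                     else np.zeros(K)),
            "rlnAccuracyTranslationsAngst": (
                (self.acc_trans * self.pixel_size) if self.acc_trans is not None
                else np.zeros(K)),
        })
        return MetadataTable(name="model_classes", df=df)

    def averages_stack(self) -> ImageStack:
        return ImageStack(self.class_averages().astype(np.float32),
                          self.pixel_size)
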