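"""Contrast transfer function (CTF) of the electron microscope.

The adopted functional form (a convention; the sign makes the function
negative at low frequency for positive, i.e. underfocus, defocus, so
images are compared against CTF-multiplied references rather than
phase-flipped data):

    CTF(s, theta) = -( sqrt(1 - A^2) * sin(gamma) + A * cos(gamma) )
    gamma(s, theta) = pi * lambda * dz(theta) * s^2
                      - (pi / 2) * Cs * lambda^3 * s^4 + phase_shift
    dz(theta) = (dz_u + dz_v) / 2 + (dz_u - dz_v) / 2 * cos(2 (theta - alpha))

with s the spatial frequency magnitude in 1/Angstrom, theta its azimuth,
A the amplitude contrast fraction and alpha the astigmatism angle.  The
relativistic electron wavelength is computed from the acceleration voltage.
No envelope (B-factor) is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CtfParams", "electron_wavelength", "ctf_eval", "ctf_grid"]


@dataclass(frozen=True)
class CtfParams:
    """Per-particle CTF parameters (units mirror common particle metadata)."""

    defocus_u: float            # Angstrom
    defocus_v: float            # Angstrom
    defocus_angle: float = 0.0  # degrees
    voltage: float = 300.0      # kV
    cs: float = 2.7             # spherical aberration, mm
    amplitude_contrast: float = 0.1   # fraction in [0, 1]
    phase_shift: float = 0.0    # radians

    def __post_init__(self) -> None:
        if not self.voltage > 0:
            raise ValueError(f"voltage must be positive, got {self.voltage}")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError(
                f"amplitude contrast must lie in [0, 1], got {self.amplitude_contrast}")


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom for a voltage in kV."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


def ctf_eval(params: CtfParams, freq_y: np.ndarray, freq_x: np.ndarray) -> np.ndarray:
    """Evaluate the CTF on spatial frequencies given in 1/Angstrom.

    ``freq_y``/``freq_x`` are broadcastable arrays of frequency components;
    output values lie in [-1, 1].
    """
    fy = np.asarray(freq_y, dtype=np.float64)
    fx = np.asarray(freq_x, dtype=np.float64)
    s2 = fy * fy + fx * fx
    if np.any(s2 < 0):
        raise ValueError("negative squared frequency magnitude")
    theta = np.arctan2(fy, fx)
    lam = electron_wavelength(params.voltage)
    alpha = np.deg2rad(params.defocus_angle)
    dz = (0.5 * (params.defocus_u + params.defocus_v)
          + 0.5 * (params.defocus_u - params.defocus_v) * np.cos(2.0 * (theta - alpha)))
    cs_angstrom = params.cs * 1e7  # mm -> Angstrom
    gamma = (np.pi * lam * dz * s2
             - 0.5 * np.pi * cs_angstrom * lam ** 3 * s2 * s2
             + params.phase_shift)
    a = params.amplitude_contrast
    return -(np.sqrt(1.0 - a * a) * np.sin(gamma) + a * np.cos(gamma))


def ctf_grid(params: CtfParams, box: int, pixel_size: float) -> np.ndarray:
    """CTF evaluated on the packed active half-plane grid (float32)."""
    from .grids import fourier_grid

    g = fourier_grid(box)
    fy, fx = g.freq_in_inv_angstrom(pixel_size)
    return ctf_eval(params, fy, fx).astype(np.float32)
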