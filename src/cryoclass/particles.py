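"""Particle stacks: images plus per-particle CTF metadata and half-set labels."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ctf import CtfParams, ctf_eval
from .grids import fourier_grid, rfft_image
from .mrc import ImageStack, read_mrc, write_mrc
from .star import MetadataTable, read_star, write_star

__all__ = ["ParticleStack", "read_particles", "write_particles"]

_CTF_COLUMNS = ["rlnDefocusU", "rlnDefocusV", "rlnDefocusAngle", "rlnVoltage",
                "rlnSphericalAberration", "rlnAmplitudeContrast"]


@dataclass
class ParticleStack:
    """N particle images with CTF metadata and half-set labels.

    ``meta`` carries one row per particle with RELION-style column names
    (rlnDefocusU/V [A], rlnDefocusAngle [deg], rlnVoltage [kV],
    rlnSphericalAberration [mm], rlnAmplitudeContrast, rlnRandomSubset).
    """

    images: ImageStack
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.meta) != self.images.n_images:
            raise ValueError(
                f"metadata rows ({len(self.meta)}) != images ({self.images.n_images})")
        missing = [c for c in _CTF_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        if "rlnRandomSubset" not in self.meta.columns:
            self.meta = self.meta.copy()
            self.meta["rlnRandomSubset"] = (np.arange(len(self.meta)) % 2) + 1

    def __len__(self) -> int:
        return self.images.n_images

    @property
    def box(self) -> int:
        return self.images.box

    @property
    def pixel_size(self) -> float:
        return self.images.pixel_size

    @property
    def halfset(self) -> np.ndarray:
        """Half-set label per particle (1 or 2)."""
        return self.meta["rlnRandomSubset"].to_numpy(dtype=np.int64)

    def ctf_params(self, i: int) -> CtfParams:
        row = self.meta.iloc[i]
        return CtfParams(defocus_u=float(row.rlnDefocusU),
                         defocus_v=float(row.rlnDefocusV),
                         defocus_angle=float(row.rlnDefocusAngle),
                         voltage=float(row.rlnVoltage),
                         cs=float(row.rlnSphericalAberration),
                         amplitude_contrast=float(row.rlnAmplitudeContrast))

    def fourier_half(self) -> np.ndarray:
        """Half-plane Fourier transforms, (N, box, box//2+1) complex64,
        beyond-Nyquist coefficients zeroed."""
        g = fourier_grid(self.box)
        xh = rfft_image(self.images.data.astype(np.float32)).astype(np.complex64)
        xh[:, ~g.active_half] = 0.0
        return xh

    def ctf_half(self) -> np.ndarray:
        """Per-particle CTF on the half-plane grid, (N, box, box//2+1) f32."""
        g = fourier_grid(self.box)
        fy, fx = g.freq_in_inv_angstrom(self.pixel_size)
        fy_h = np.zeros((self.box, self.box // 2 + 1))
        fx_h = np.zeros_like(fy_h)
        fy_h.ravel()[g.act_idx] = fy
        fx_h.ravel()[g.act_idx] = fx
        out = np.empty((len(self), self.box, self.box // 2 + 1), np.float32)
        for i in range(len(self)):
            c = ctf_eval(self.ctf_params(i), fy_h, fx_h).astype(np.float32)
            c[~g.active_half] = 0.0
            out[i] = c
        return out


def write_particles(stack: ParticleStack, out_dir: str | Path,
                    basename: str = "particles", mode: int = 2) -> tuple[Path, Path]:
    """Write an .mrcs image stack and a particles .star next to it."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mrcs = out_dir / f"{basename}.mrcs"
    star = out_dir / f"{basename}.star"
    write_mrc(stack.images, mrcs, mode=mode)
    meta = stack.meta.copy()
    meta.insert(0, "rlnImageName",
                [f"{i + 1:06d}@{mrcs.name}" for i in range(len(stack))])
    write_star(MetadataTable(name="particles", df=meta), star)
    return mrcs, star


def read_particles(star_path: str | Path) -> ParticleStack:
    """Load a particle stack from a particles .star (images resolved
    relative to the star file's directory)."""
    star_path = Path(star_path)
    tables = {t.name: t for t in read_star(star_path)}
    if "particles" not in tables:
        raise ValueError(f"no 'particles' block in {star_path}")
    meta = tables["particles"].df.copy()
    names = meta["rlnImageName"].astype(str)
    files = names.str.split("@").str[1].unique()
    if len(files) != 1:
        raise ValueError("particles must reference a single .mrcs stack")
    images = read_mrc(star_path.parent / files[0])
    order = names.str.split("@").str[0].astype(int).to_numpy() - 1
    images = ImageStack(images.data[order], images.pixel_size, images.mode)
    return ParticleStack(images=images, meta=meta.drop(columns=["rlnImageName"]))
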