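"""Reading and writing of MRC/MRCS image stacks.

Implements the 1024-byte MRC2014 header with storage modes 0 (int8),
1 (int16), 2 (float32), 6 (uint16) and 12 (IEEE 754 half precision,
float16).  Stacks are stored as (section, row, column) with the section
count in NZ, the convention used for single-particle .mrcs stacks.  The
pixel size is encoded through the cell dimensions (CELLA = NX * pixel
size) and the sampling grid MX = NX.

Only a single (empty) extended header is supported; data are always
little-endian on disk.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ImageStack", "MrcFormatError", "UnsupportedModeError", "read_mrc", "write_mrc"]

HEADER_SIZE = 1024
# MRC mode tag -> on-disk dtype (little endian)
_MODE_DTYPES = {
    0: np.dtype("<i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
    12: np.dtype("<f2"),
}
_WRITE_MODES = (2, 12)
_HALF_MAX = 65504.0  # largest finite float16


class MrcFormatError(ValueError):
    """Malformed MRC header or truncated data."""


class UnsupportedModeError(MrcFormatError):
    """MRC mode tag outside the supported set."""


@dataclass
class ImageStack:
    """A stack of real-valued square images with a physical pixel size.

    Parameters
    ----------
    data:
        Array of shape (n_images, box, box), densities in arbitrary units.
    pixel_size:
        Pixel size in Angstrom per pixel; must be positive.
    mode:
        MRC storage mode tag the stack was read from / will be written as.
    """

    data: np.ndarray
    pixel_size: float
    mode: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise ValueError("ImageStack data must be (n_images, box, box)")
        n, box, _ = self.data.shape
        if n < 1:
            raise ValueError("ImageStack needs at least one image")
        if box < 16 or box % 2:
            raise ValueError(f"box must be even and >= 16, got {box}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def n_images(self) -> int:
        return self.data.shape[0]

    @property
    def box(self) -> int:
        return self.data.shape[1]


def _pack_header(nx: int, ny: int, nz: int, mode: int, pixel_size: float,
                 dmin: float, dmax: float, dmean: float, rms: float) -> bytes:
    h = bytearray(HEADER_SIZE)
    struct.pack_into("<10i", h, 0,
                     nx, ny, nz, mode,
                     0, 0, 0,          # NXSTART..NZSTART
                     nx, ny, nz)       # MX, MY, MZ
    struct.pack_into("<6f", h, 40,
                     nx * pixel_size, ny * pixel_size, nz * pixel_size,
                     90.0, 90.0, 90.0)
    struct.pack_into("<3i", h, 64, 1, 2, 3)  # MAPC, MAPR, MAPS
    struct.pack_into("<3f", h, 76, dmin, dmax, dmean)
    struct.pack_into("<2i", h, 88, 1, 0)     # ISPG (stack of 2D images), NSYMBT
    h[208:212] = b"MAP "
    h[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian machine stamp
    struct.pack_into("<f", h, 216, rms)
    struct.pack_into("<i", h, 220, 0)        # NLABL
    return bytes(h)


def write_mrc(stack: ImageStack, path: str | Path, mode: int = 2) -> None:
    """Write *stack* to *path* in MRC mode 2 (float32) or 12 (float16).

    Raises
    ------
    ValueError
        If *mode* is not 2 or 12.
    OverflowError
        If mode 12 is requested and any value's magnitude exceeds the
        largest finite half-precision number (infinities included).
    """
    if mode not in _WRITE_MODES:
        raise ValueError(f"write_mrc supports modes {_WRITE_MODES}, got {mode}")
    data = np.asarray(stack.data, dtype=np.float32)
    if mode == 12:
        bad = np.abs(data) > _HALF_MAX
        if np.any(bad | np.isnan(data)):
            raise OverflowError(
                "values exceed IEEE 754 half-precision range for MRC mode 12")
    n, box, _ = data.shape
    finite = data[np.isfinite(data)]
    dmin = float(finite.min()) if finite.size else 0.0
    dmax = float(finite.max()) if finite.size else 0.0
    dmean = float(finite.mean()) if finite.size else 0.0
    rms = float(finite.std()) if finite.size else 0.0
    header = _pack_header(box, box, n, mode, stack.pixel_size, dmin, dmax, dmean, rms)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(data.astype(_MODE_DTYPES[mode])).tobytes())


def read_mrc(path: str | Path) -> ImageStack:
    """Read an MRC/MRCS file into an :class:`ImageStack`.

    Supports modes 0, 1, 2, 6 and 12; data axes are returned ordered
    (image, row, column).  The pixel size is recovered from the cell
    dimension CELLA_X / MX.
    """
    raw = Path(path).read_bytes()
    if len(raw) < HEADER_SIZE:
        raise MrcFormatError(f"file shorter than the {HEADER_SIZE}-byte MRC header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cella = struct.unpack_from("<3f", raw, 40)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if nx <= 0 or ny <= 0 or nz <= 0:
        raise MrcFormatError(f"non-positive dimensions NX={nx} NY={ny} NZ={nz}")
    if mode not in _MODE_DTYPES:
        raise UnsupportedModeError(f"unsupported MRC mode {mode}")
    if nsymbt < 0:
        raise MrcFormatError(f"negative extended header size NSYMBT={nsymbt}")
    dtype = _MODE_DTYPES[mode]
    expected = HEADER_SIZE + nsymbt + nx * ny * nz * dtype.itemsize
    if len(raw) < expected:
        raise MrcFormatError(
            f"truncated data: expected {expected} bytes, file has {len(raw)}")
    if mx > 0 and cella[0] > 0:
        pixel_size = cella[0] / mx
    elif cella[0] > 0:
        pixel_size = cella[0] / nx
    else:
        pixel_size = 1.0
    data = np.frombuffer(raw, dtype=dtype, count=nx * ny * nz,
                         offset=HEADER_SIZE + nsymbt)
    data = data.reshape(nz, ny, nx).astype(np.float32)
    return ImageStack(data=data, pixel_size=float(pixel_size), mode=mode)
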