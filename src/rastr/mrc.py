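"""Minimal MRC2014 reader/writer for image stacks and volumes.

Supports the subset of the format this package exchanges: mode 2 (32-bit
float) data written natively, modes 0/1/2/6 read and promoted to float32.
Image stacks are stored with ``ispg=0`` (nz = number of images); volumes
with ``ispg=1``.  Data layout is ``arr[z, y, x]`` / ``arr[i, y, x]``.
"""

from __future__ import annotations

import os

import numpy as np

HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


class MrcFormatError(ValueError):
    """Raised when a file is not a readable MRC of the supported subset."""


def read_mrc(path: str | os.PathLike) -> tuple[np.ndarray, float, bool]:
    """Read an MRC file.

    Returns
    -------
    data : (nz, ny, nx) float32 array
    pixel_size : float, Angstrom per pixel (x spacing)
    is_volume : bool, True when the file declares a 3D map (ispg >= 1)
    """
    with open(path, "rb") as fh:
        header = fh.read(HEADER_SIZE)
        if len(header) < HEADER_SIZE:
            raise MrcFormatError(f"{path}: truncated MRC header")
        ints = np.frombuffer(header, dtype="<i4", count=56)
        floats = np.frombuffer(header, dtype="<f4", count=56)
        nx, ny, nz, mode = (int(v) for v in ints[:4])
        mx, my, mz = (int(v) for v in ints[7:10])
        cella = floats[10:13]
        ispg = int(ints[22])
        nsymbt = int(ints[23])
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise MrcFormatError(f"{path}: missing MAP identifier")
        if min(nx, ny, nz) <= 0:
            raise MrcFormatError(f"{path}: non-positive dimensions {nx}x{ny}x{nz}")
        if mode not in _MODE_DTYPES:
            raise MrcFormatError(f"{path}: unsupported mode {mode}")
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        fh.seek(HEADER_SIZE + nsymbt)
        raw = fh.read(nx * ny * nz * dtype.itemsize)
        expected = nx * ny * nz * dtype.itemsize
        if len(raw) < expected:
            raise MrcFormatError(
                f"{path}: header declares {nz} sections of {ny}x{nx} but data is short"
            )
    data = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx).astype(np.float32)
    pixel_size = float(cella[0] / mx) if mx > 0 and cella[0] > 0 else 1.0
    return data, pixel_size, ispg >= 1


def write_mrc(
    path: str | os.PathLike,
    data: np.ndarray,
    pixel_size: float,
    is_volume: bool = False,
) -> None:
    """Write a float32 (mode 2) MRC stack or volume."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    nz, ny, nx = data.shape
    header = np.zeros(256, dtype="<i4")
    fheader = header.view("<f4")
    header[0:3] = (nx, ny, nz)
    header[3] = 2  # mode 2: float32
    header[7:10] = (nx, ny, nz)  # sampling grid
    fheader[10:13] = (nx * pixel_size, ny * pixel_size, nz * pixel_size)
    fheader[13:16] = 90.0
    header[16:19] = (1, 2, 3)  # column/row/section axis order x,y,z
    fheader[19] = float(data.min())
    fheader[20] = float(data.max())
    fheader[21] = float(data.mean())
    header[22] = 1 if is_volume else 0  # ispg
    header[23] = 0  # nsymbt
    header[52] = int.from_bytes(b"MAP ", "little")
    header[53] = int.from_bytes(bytes((0x44, 0x44, 0, 0)), "little")  # little-endian stamp
    fheader[54] = float(data.std())
    header[55] = 0  # nlabl
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(data.tobytes())
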