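"""Core containers and file I/O for 2D image stacks, 3D volumes, and metadata.

All pipeline stages exchange data through these types:

* :class:`Image2D` — a single real-valued pixel grid with a physical pixel
  size in Angstrom/pixel.
* :class:`ImageStack` — an ordered stack of same-sized images plus a
  metadata table with exactly one row per image.
* :class:`Volume3D` — a cubic density grid (tube axis along z by
  convention).

Stacks and volumes are stored as MRC2014 files (mode 2, 32-bit float);
metadata travels in a STAR-format sidecar table using RELION-style column
names where a standard name exists.  Particle picks are written as
plain-text tab-separated coordinate files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mrc import MrcFormatError, read_mrc, write_mrc
from .star import read_star, write_star

__all__ = [
    "FormatError",
    "Image2D",
    "ImageStack",
    "Volume3D",
    "empty_metadata",
    "read_stack",
    "write_stack",
    "read_volume",
    "write_volume",
    "read_picks",
    "write_picks",
]

FormatError = MrcFormatError

#: Internal metadata column -> STAR tag.  Columns without an entry are
#: exported with a camel-cased ``rastr`` prefix.
STAR_NAME_MAP = {
    "segment_id": "rastrSegmentId",
    "micrograph_id": "rlnMicrographName",
    "origin_x": "rlnCoordinateX",
    "origin_y": "rlnCoordinateY",
    "psi_deg": "rlnAnglePsi",
    "theta_deg": "rlnAngleTilt",
    "phi_deg": "rlnAngleRot",
    "shift_x_px": "rlnOriginX",
    "shift_y_px": "rlnOriginY",
    "defocus_A": "rlnDefocusU",
    "amp_contrast": "rlnAmplitudeContrast",
}
_STAR_NAME_INV = {v: k for k, v in STAR_NAME_MAP.items()}

ALIGNMENT_COLUMNS = ("psi_deg", "theta_deg", "phi_deg", "shift_x_px", "shift_y_px")


@dataclass
class Image2D:
    """A 2D pixel grid with physical pixel size (Angstrom/pixel)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D requires a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D pixels must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def require_square(self) -> int:
        ny, nx = self.pixels.shape
        if ny != nx:
            raise ValueError(f"operation requires a square image, got {ny}x{nx}")
        return nx


@dataclass
class ImageStack:
    """Ordered same-sized images plus one metadata row per image."""

    data: np.ndarray  # (n, ny, nx)
    pixel_size: float
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be 3D (n, ny, nx)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.metadata is None or len(self.metadata) == 0:
            self.metadata = empty_metadata(len(self.data))
        if len(self.metadata) != len(self.data):
            raise ValueError(
                f"metadata has {len(self.metadata)} rows for {len(self.data)} images"
            )
        self.metadata = self.metadata.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def image(self, i: int) -> Image2D:
        return Image2D(self.data[i], self.pixel_size)

    def copy_with(self, data: np.ndarray | None = None,
                  metadata: pd.DataFrame | None = None) -> "ImageStack":
        return ImageStack(
            self.data.copy() if data is None else data,
            self.pixel_size,
            (self.metadata if metadata is None else metadata).copy(),
        )


@dataclass
class Volume3D:
    """Cubic density grid; tube axis along the z (first) axis."""

    voxels: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        nz, ny, nx = self.voxels.shape
        if not (nz == ny == nx):
            raise ValueError(f"Volume3D must be cubic, got {nz}x{ny}x{nx}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("Volume3D voxels must be finite")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def size(self) -> int:
        return self.voxels.shape[0]


def empty_metadata(n: int) -> pd.DataFrame:
    return pd.DataFrame({"segment_id": np.arange(n, dtype=int)})


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".star")


def _camel(name: str) -> str:
    return "rastr" + "".join(p.capitalize() for p in re.split(r"[_\W]+", name) if p)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an MRC image stack plus its STAR metadata sidecar."""
    if len(stack) == 0:
        raise ValueError("refusing to write an empty stack")
    path = Path(path)
    write_mrc(path, stack.data, stack.pixel_size, is_volume=False)
    df = stack.metadata.rename(
        columns=lambda c: STAR_NAME_MAP.get(c, c if c.startswith("rastr") else _camel(c))
    )
    write_star(_sidecar(path), df)


def read_stack(path: str | Path) -> ImageStack:
    """Read an MRC image stack; metadata sidecar is optional."""
    path = Path(path)
    data, pixel_size, _ = read_mrc(path)
    sidecar = _sidecar(path)
    if sidecar.exists():
        df = read_star(sidecar)
        inv = {}
        for col in df.columns:
            if col in _STAR_NAME_INV:
                inv[col] = _STAR_NAME_INV[col]
            elif col.startswith("rastr") and col != "rastrSegmentId":
                snake = re.sub(r"(?<!^)(?=[A-Z])", "_", col[len("rastr"):]).lower()
                inv[col] = snake
        metadata = df.rename(columns=inv)
    else:
        metadata = empty_metadata(len(data))
    return ImageStack(data, pixel_size, metadata)


def write_volume(vol: Volume3D, path: str | Path) -> None:
    write_mrc(path, vol.voxels, vol.voxel_size, is_volume=True)


def read_volume(path: str | Path) -> Volume3D:
    data, voxel_size, _ = read_mrc(path)
    nz, ny, nx = data.shape
    if not (nz == ny == nx):
        raise FormatError(f"{path}: volume must be cubic, got {nz}x{ny}x{nx}")
    return Volume3D(data, voxel_size)


_PICK_COLUMNS = ["micrograph_id", "global_x", "global_y", "score",
                 "segment_id", "local_x", "local_y"]


def write_picks(picks: pd.DataFrame, path: str | Path) -> None:
    """Write picks as a plain-text TSV coordinate file."""
    cols = [c for c in _PICK_COLUMNS if c in picks.columns]
    picks.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.3f")


def read_picks(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
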