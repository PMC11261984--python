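"""Volume and coordinate plumbing: MRC I/O, orthogonal slicing, normalization.

Conventions used throughout the package
---------------------------------------
* A tomogram is a ``(D, H, W)`` array indexed ``(z, y, x)``, 0-based.
  In MRC terms: sections -> z, rows -> y, columns -> x.
* Slices through the three orthogonal views:

  ====  ===========  ============  =========================
  axis  image shape  axis labels   pixel (row, col) -> voxel
  ====  ===========  ============  =========================
  z     (H, W)       (y, x)        (index, row, col)
  y     (D, W)       (z, x)        (row, index, col)
  x     (D, H)       (z, y)        (row, col, index)
  ====  ===========  ============  =========================

* All intervals are half-open and all coordinates 0-based, including in
  CSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

AXES = ("z", "y", "x")

#: (row_label, col_label) of the 2D image extracted along each axis
SLICE_AXIS_LABELS = {"z": ("y", "x"), "y": ("z", "x"), "x": ("z", "y")}


class VolumeError(ValueError):
    """Raised for malformed volumes, masks or MRC files."""


@dataclass
class Tomogram:
    """A 3D density volume with optional physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (D, H, W)
        Scalar density grid, indexed (z, y, x).
    voxel_size : float, optional
        Isotropic voxel spacing in Angstrom, carried through from the
        MRC header when available.
    """

    voxels: np.ndarray
    voxel_size: Optional[float] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise VolumeError(f"tomogram must be 3D, got ndim={v.ndim}")
        if any(s < 1 for s in v.shape):
            raise VolumeError(f"all extents must be >= 1, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise VolumeError("tomogram contains non-finite voxels")
        self.voxels = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class PointPrompt:
    """An integer voxel coordinate marking one particle."""

    z: int
    y: int
    x: int

    def validate(self, shape: tuple[int, int, int]) -> None:
        for c, ax, ext in zip((self.z, self.y, self.x), AXES, shape):
            if not 0 <= c < ext:
                raise VolumeError(
                    f"prompt {ax}={c} outside volume extent [0, {ext})"
                )

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.z, self.y, self.x)


@dataclass
class Image2D:
    """A 2D slice extracted from a tomogram."""

    pixels: np.ndarray
    axis_labels: tuple[str, str] = ("y", "x")

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise VolumeError(f"image must be 2D, got ndim={p.ndim}")
        self.pixels = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# MRC I/O (via gemmi; MRC2014 / CCP4 map format)
# ---------------------------------------------------------------------------

_SUPPORTED_MODES = {0, 1, 2, 12}


def _check_header(path: Path) -> None:
    hdr = gemmi.read_ccp4_header(str(path))
    nz = hdr.header_i32(3)
    mode = hdr.header_i32(4)
    ispg = hdr.header_i32(23)
    if mode not in _SUPPORTED_MODES:
        raise VolumeError(f"unsupported MRC mode {mode} in {path}")
    if nz <= 1 or ispg == 0:
        raise VolumeError(f"{path} is not a 3D volume (2D image or stack)")


def read_tomogram(path: str | Path) -> Tomogram:
    """Read an MRC volume into a ``(z, y, x)``-indexed :class:`Tomogram`.

    MRC sections map to z, rows to y, columns to x, regardless of the
    on-disk axis permutation (MAPC/MAPR/MAPS are normalized on read).
    Raises :class:`VolumeError` on a missing file, a non-3D map, or an
    unsupported data mode.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such file: {path}")
    _check_header(path)
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    # gemmi grid arrays are indexed (x, y, z); transpose to (z, y, x)
    arr = np.array(m.grid, copy=True).transpose(2, 1, 0)
    voxel_size: Optional[float] = None
    nx = m.grid.nu
    if nx and m.grid.unit_cell.a > 0:
        vs = m.grid.unit_cell.a / nx
        if vs > 0 and abs(vs - 1.0) > 1e-9:
            voxel_size = float(vs)
    return Tomogram(arr.astype(np.float32, copy=False), voxel_size)


def _write_grid(path: Path, data: np.ndarray, voxel_size: Optional[float],
                as_mask: bool) -> None:
    # gemmi expects (x, y, z) fastest-to-slowest ordering
    xyz = np.ascontiguousarray(data.transpose(2, 1, 0))
    if as_mask:
        m = gemmi.Ccp4Mask()
        m.grid = gemmi.Int8Grid(xyz.astype(np.int8))
    else:
        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(xyz.astype(np.float32))
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    vs = voxel_size if voxel_size is not None else 1.0
    nz, ny, nx = data.shape
    m.grid.set_unit_cell(gemmi.UnitCell(nx * vs, ny * vs, nz * vs, 90, 90, 90))
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def write_volume(path: str | Path, data: np.ndarray,
                 voxel_size: Optional[float] = None) -> None:
    """Write a float volume (MRC mode 2) indexed (z, y, x)."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise VolumeError("volume must be 3D")
    _write_grid(Path(path), data, voxel_size, as_mask=False)


def write_mask(path: str | Path, mask: np.ndarray,
               voxel_size: Optional[float] = None) -> None:
    """Write a binary mask volume as an int8 MRC (mode 0).

    Voxel values must be in {0, 1} (booleans accepted); anything else
    raises :class:`VolumeError`.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise VolumeError("mask must be 3D")
    if mask.dtype != np.bool_:
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise VolumeError("non-binary mask: values outside {0, 1}")
    _write_grid(Path(path), mask.astype(np.int8), voxel_size, as_mask=True)


def write_labels(path: str | Path, labels: np.ndarray,
                 voxel_size: Optional[float] = None) -> None:
    """Write a small integer label volume (MRC mode 0; labels <= 127)."""
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise VolumeError("label volume must be 3D")
    if labels.min() < 0 or labels.max() > 127:
        raise VolumeError("labels must fit in int8 (0..127)")
    _write_grid(Path(path), labels.astype(np.int8), voxel_size, as_mask=True)


# ---------------------------------------------------------------------------
# Orthogonal slicing
# ---------------------------------------------------------------------------

def extract_slice(t: Tomogram | np.ndarray, axis: str, index: int) -> Image2D:
    """Extract the 2D plane perpendicular to ``axis`` at ``index``.

    See the module docstring for the (row, col) -> voxel mapping of each
    view; :func:`slice_to_voxel` implements the inverse map.
    """
    vol = t.voxels if isinstance(t, Tomogram) else np.asarray(t)
    if axis not in AXES:
        raise VolumeError(f"axis must be one of {AXES}, got {axis!r}")
    ax = AXES.index(axis)
    if not 0 <= index < vol.shape[ax]:
        raise VolumeError(
            f"slice index {index} outside axis {axis} extent "
            f"[0, {vol.shape[ax]})"
        )
    if axis == "z":
        pixels = vol[index, :, :]
    elif axis == "y":
        pixels = vol[:, index, :]
    else:
        pixels = vol[:, :, index]
    return Image2D(pixels, SLICE_AXIS_LABELS[axis])


def slice_to_voxel(axis: str, index: int, row: int, col: int
                   ) -> tuple[int, int, int]:
    """Map an (row, col) pixel of an extracted slice back to its voxel."""
    if axis == "z":
        return (index, row, col)
    if axis == "y":
        return (row, index, col)
    if axis == "x":
        return (row, col, index)
    raise VolumeError(f"axis must be one of {AXES}, got {axis!r}")


def voxel_to_slice_pixel(axis: str, z: int, y: int, x: int
                         ) -> tuple[int, tuple[int, int]]:
    """Return ``(slice index, (row, col))`` of a voxel in the given view."""
    if axis == "z":
        return z, (y, x)
    if axis == "y":
        return y, (z, x)
    if axis == "x":
        return x, (z, y)
    raise VolumeError(f"axis must be one of {AXES}, got {axis!r}")


def embed_slice_mask(volume_mask: np.ndarray, axis: str, index: int,
                     mask2d: np.ndarray) -> None:
    """OR a 2D slice mask into a 3D boolean volume, in place."""
    if axis == "z":
        volume_mask[index, :, :] |= mask2d
    elif axis == "y":
        volume_mask[:, index, :] |= mask2d
    elif axis == "x":
        volume_mask[:, :, index] |= mask2d
    else:
        raise VolumeError(f"axis must be one of {AXES}, got {axis!r}")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_slice(img: Image2D, low_pct: float = 1.0,
                    high_pct: float = 99.0) -> Image2D:
    """Percentile-clip and rescale a slice to [0, 1].

    Values are clipped to the [low_pct, high_pct] percentile range of the
    slice and mapped linearly onto [0, 1]. Cryo-ET slice intensities are
    heavy-tailed, so a modest clip keeps outlier voxels from compressing
    the usable dynamic range. A constant slice maps to all zeros.
    """
    if not low_pct < high_pct:
        raise VolumeError("low_pct must be < high_pct")
    p = np.asarray(img.pixels, dtype=np.float64)
    lo, hi = np.percentile(p, (low_pct, high_pct))
    if hi <= lo:
        return Image2D(np.zeros_like(p), img.axis_labels)
    out = (np.clip(p, lo, hi) - lo) / (hi - lo)
    return Image2D(out, img.axis_labels)
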