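"""Tri-view feature volumes and multi-resolution feature pyramids.

Every slice of the tomogram along each of the three axes is encoded with
a 2D feature encoder; each view's per-slice feature maps are bilinearly
upsampled in-plane back to the slice's pixel resolution (align-corners
convention, no interpolation along the stacking axis) and the three view
blocks are channel-concatenated into a full-resolution feature volume

    F = [Z, Y, X]  of shape  (D, H, W, 3*C).

The pyramid level at integer ratio ``r`` is the block average of the
full-resolution features over r*r*r cells (edge cells average their
partial extent), so a level's volume-weighted mean feature equals the
full-resolution mean exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .backends import Encoder
from .core_volume import AXES, Tomogram, VolumeError, extract_slice, normalize_slice


@dataclass
class FeatureVolume:
    """Full-resolution concatenated tri-view features, (D, H, W, 3C)."""

    data: np.ndarray
    view_channels: int  # channels per view block (C); blocks ordered Z, Y, X

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise VolumeError("feature volume must be 4D (D, H, W, channels)")
        if self.data.shape[3] != 3 * self.view_channels:
            raise VolumeError(
                f"channel count {self.data.shape[3]} is not 3 x "
                f"{self.view_channels}"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]


@dataclass
class FeaturePyramidLevel:
    """One pyramid level: features pooled over ratio^3 blocks."""

    ratio: int
    data: np.ndarray                      # (ceil(D/r), ceil(H/r), ceil(W/r), 3C)
    full_shape: tuple[int, int, int]      # (D, H, W) of the source volume

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Full-resolution voxel coordinates of the cell centers.

        Cell (i, j, k) maps to voxel (i*r + r//2, j*r + r//2, k*r + r//2),
        clipped to the volume (edge cells are partial).
        """
        r = self.ratio
        return tuple(
            np.minimum(np.arange(n) * r + r // 2, full - 1)
            for n, full in zip(self.grid_shape, self.full_shape)
        )  # type: ignore[return-value]

    def cell_center(self, cell: tuple[int, int, int]) -> tuple[int, int, int]:
        r = self.ratio
        return tuple(
            min(c * r + r // 2, full - 1)
            for c, full in zip(cell, self.full_shape)
        )  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Encoding and upsampling
# ---------------------------------------------------------------------------

def encode_view(t: Tomogram, axis: str, encoder: Encoder,
                norm_percentiles: tuple[float, float] = (1.0, 99.0)
                ) -> tuple[np.ndarray, int]:
    """Encode every slice along ``axis``; returns (stack, stride).

    The stack has shape (n_slices, h, w, C) where (h, w) is the encoder's
    reduced in-plane resolution.
    """
    extent = t.shape[AXES.index(axis)]
    maps = []
    for i in range(extent):
        img = normalize_slice(extract_slice(t, axis, i), *norm_percentiles)
        maps.append(encoder.encode(img).data)
    return np.stack(maps, axis=0), encoder.stride


def _linear_coords(n_in: int, n_out: int
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align-corners sample positions: i0, i1, fractional weight."""
    if n_in == 1 or n_out == 1:
        pos = np.zeros(n_out)
    else:
        pos = np.linspace(0.0, n_in - 1.0, n_out)
    i0 = np.floor(pos).astype(int)
    i0 = np.minimum(i0, n_in - 1)
    i1 = np.minimum(i0 + 1, n_in - 1)
    return i0, i1, pos - i0


def upsample_view(stack: np.ndarray, axis: str,
                  target_shape: tuple[int, int, int]) -> np.ndarray:
    """Bilinearly upsample each slice's feature map in-plane and arrange
    the stack into (z, y, x, C) voxel order.

    The stacking axis must already equal its target extent (one feature
    map per slice); only the two in-plane axes are interpolated.
    """
    D, H, W = target_shape
    plane = {"z": (H, W), "y": (D, W), "x": (D, H)}[axis]
    stack_extent = {"z": D, "y": H, "x": W}[axis]
    if stack.shape[0] != stack_extent:
        raise VolumeError(
            f"stacking axis extent {stack.shape[0]} != target {stack_extent}"
        )
    n, h, w, c = stack.shape
    r0, r1, rf = _linear_coords(h, plane[0])
    rows = stack[:, r0, :, :] * (1 - rf)[None, :, None, None] \
        + stack[:, r1, :, :] * rf[None, :, None, None]
    c0, c1, cf = _linear_coords(w, plane[1])
    full = rows[:, :, c0, :] * (1 - cf)[None, None, :, None] \
        + rows[:, :, c1, :] * cf[None, None, :, None]
    # rearrange (slice, row, col, C) into (z, y, x, C)
    if axis == "z":            # rows are y, cols are x
        return full
    if axis == "y":            # slices are y, rows are z, cols are x
        return full.transpose(1, 0, 2, 3)
    # axis == "x": slices are x, rows are z, cols are y
    return full.transpose(1, 2, 0, 3)


def build_feature_volume(z_block: np.ndarray, y_block: np.ndarray,
                         x_block: np.ndarray) -> FeatureVolume:
    """Channel-concatenate the three (D, H, W, C) view blocks as [Z, Y, X]."""
    if not (z_block.shape == y_block.shape == x_block.shape):
        raise VolumeError(
            f"view block shapes differ: {z_block.shape}, {y_block.shape}, "
            f"{x_block.shape}"
        )
    data = np.concatenate([z_block, y_block, x_block], axis=3)
    return FeatureVolume(data, view_channels=z_block.shape[3])


def encode_tomogram(t: Tomogram, encoder: Encoder,
                    norm_percentiles: tuple[float, float] = (1.0, 99.0)
                    ) -> FeatureVolume:
    """Convenience: encode all three views, upsample, and concatenate."""
    blocks = {}
    for axis in AXES:
        stack, _ = encode_view(t, axis, encoder, norm_percentiles)
        blocks[axis] = upsample_view(stack, axis, t.shape).astype(np.float32)
    return build_feature_volume(blocks["z"], blocks["y"], blocks["x"])


# ---------------------------------------------------------------------------
# Pyramid
# ---------------------------------------------------------------------------

def _block_mean_3d(a: np.ndarray, r: int) -> np.ndarray:
    """Average over r^3 blocks along the first three axes; edge blocks
    average their partial extent. Trailing axes are preserved."""
    out = a.astype(np.float64, copy=False)
    counts = 1.0
    for ax in range(3):
        idx = np.arange(0, out.shape[ax], r)
        n_full = np.minimum(idx + r, a.shape[ax]) - idx
        out = np.add.reduceat(out, idx, axis=ax)
        shape = [1] * out.ndim
        shape[ax] = len(idx)
        counts = counts * n_full.reshape(shape)
    return out / counts


def build_pyramid(f: FeatureVolume, ratios: Sequence[int]
                  ) -> list[FeaturePyramidLevel]:
    """Build pyramid levels at the given ratios, ordered coarse to fine.

    Ratios must be positive integers in strictly decreasing order (the
    traversal order of hierarchical matching).
    """
    ratios = list(ratios)
    if not ratios:
        raise VolumeError("ratio list must be nonempty")
    if any(int(r) != r or r < 1 for r in ratios):
        raise VolumeError(f"ratios must be positive integers: {ratios}")
    if any(a <= b for a, b in zip(ratios, ratios[1:])):
        raise VolumeError(f"ratios must be strictly decreasing: {ratios}")
    levels = []
    for r in ratios:
        if r == 1:
            data = f.data.astype(np.float64, copy=False)
        else:
            data = _block_mean_3d(f.data, int(r))
        levels.append(FeaturePyramidLevel(int(r), data, f.grid_shape))
    return levels
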