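"""Prompt-based 3D instance segmentation by cross-plane self-prompting.

A single point prompt selects one particle. The three orthogonal planes
through the prompt are segmented with the point prompt; each of the six
axis directions is then walked slice by slice, re-prompting the 2D
segmenter with the previous slice's mask and its peak-confidence point.
A direction stops when the new mask's IoU with the previous accepted
mask drops below ``tau_iou`` (the inconsistent mask is discarded), when
the segmenter returns an empty mask, or at the volume boundary. The 3D
instance mask is the voxel-wise union of the three initial plane masks
and all accepted propagated masks.

The six directional walks are independent: +/-z are seeded from the
YX-plane segmentation, +/-y from the ZX-plane, +/-x from the ZY-plane.
If an initial plane's mask is empty, the two directions it would seed
are skipped, but the other planes still run.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .backends import Segmenter
from .core_volume import (
    AXES,
    PointPrompt,
    Tomogram,
    VolumeError,
    embed_slice_mask,
    extract_slice,
    normalize_slice,
    voxel_to_slice_pixel,
)


def compute_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two equal-shape binary masks.

    Defined as 0 when both masks are empty (this forces propagation to
    stop on consecutive empty masks).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise VolumeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    inter = int(np.count_nonzero(a & b))
    return inter / union


@dataclass
class PropagationStep:
    index: int                      # slice index along the walked axis
    mask2d: np.ndarray
    peak: tuple[int, int]
    iou_with_prev: float


@dataclass
class PropagationTrace:
    """Record of one directional walk: accepted slices and why it ended."""

    axis: str
    direction: int
    steps: list[PropagationStep] = field(default_factory=list)
    stop_reason: str = "volume boundary"

    def to_rows(self) -> list[dict]:
        rows = [
            {
                "axis": self.axis,
                "direction": self.direction,
                "slice": s.index,
                "mask_area": int(np.count_nonzero(s.mask2d)),
                "iou_with_prev": s.iou_with_prev,
                "stop_reason": "",
            }
            for s in self.steps
        ]
        rows.append(
            {"axis": self.axis, "direction": self.direction, "slice": -1,
             "mask_area": 0, "iou_with_prev": float("nan"),
             "stop_reason": self.stop_reason}
        )
        return rows


@dataclass
class InstanceMask3D:
    """Binary 3D mask of one prompted or proposed particle instance."""

    data: np.ndarray                               # bool, (D, H, W)
    prompt: Optional[PointPrompt] = None
    traces: list[PropagationTrace] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def count(self) -> int:
        return int(np.count_nonzero(self.data))

    def bounding_box_extents(self) -> Optional[tuple[int, int, int]]:
        """Per-axis extents of the tight bounding box, or None if empty."""
        if self.is_empty:
            return None
        idx = np.nonzero(self.data)
        return tuple(int(ax.max() - ax.min() + 1) for ax in idx)  # type: ignore


def propagate_direction(
    t: Tomogram,
    axis: str,
    direction: int,
    start_index: int,
    seed_peak: tuple[int, int],
    seed_mask: np.ndarray,
    segmenter: Segmenter,
    tau_iou: float = 0.5,
    norm_percentiles: tuple[float, float] = (1.0, 99.0),
) -> PropagationTrace:
    """Walk slices from ``start_index + direction``, re-prompting each
    slice with the previous slice's (peak point, mask).

    The mask that triggers the IoU stop is *not* included in the trace's
    accepted steps.
    """
    if direction not in (-1, 1):
        raise VolumeError("direction must be +1 or -1")
    if not seed_mask.any():
        raise VolumeError("seed mask must be nonempty")
    extent = t.shape[AXES.index(axis)]
    trace = PropagationTrace(axis=axis, direction=direction)
    prev_mask, prev_peak = seed_mask, seed_peak
    index = start_index + direction
    while 0 <= index < extent:
        img = normalize_slice(extract_slice(t, axis, index),
                              *norm_percentiles)
        res = segmenter.segment(img, point=prev_peak, mask_prompt=prev_mask)
        if res.is_empty:
            trace.stop_reason = "empty mask"
            return trace
        iou = compute_iou(res.mask2d, prev_mask)
        if iou < tau_iou:
            trace.stop_reason = "IoU below threshold"
            return trace
        trace.steps.append(
            PropagationStep(index, res.mask2d, res.peak, iou)
        )
        prev_mask, prev_peak = res.mask2d, res.peak
        index += direction
    trace.stop_reason = "volume boundary"
    return trace


def segment_from_point(
    t: Tomogram,
    p: PointPrompt,
    segmenter: Segmenter,
    tau_iou: float = 0.5,
    norm_percentiles: tuple[float, float] = (1.0, 99.0),
    keep_traces: bool = False,
) -> InstanceMask3D:
    """Segment the particle at point prompt ``p`` into a 3D instance mask.

    Runs the initial tri-plane segmentation, the six directional walks,
    and unions everything. Returns an empty mask if all three initial
    plane segmentations are empty.
    """
    p.validate(t.shape)
    volume_mask = np.zeros(t.shape, dtype=bool)
    traces: list[PropagationTrace] = []

    for axis in AXES:
        index, pixel = voxel_to_slice_pixel(axis, p.z, p.y, p.x)
        img = normalize_slice(extract_slice(t, axis, index),
                              *norm_percentiles)
        res = segmenter.segment(img, point=pixel)
        if res.is_empty:
            continue
        embed_slice_mask(volume_mask, axis, index, res.mask2d)
        for direction in (1, -1):
            trace = propagate_direction(
                t, axis, direction, index, res.peak, res.mask2d,
                segmenter, tau_iou, norm_percentiles,
            )
            for step in trace.steps:
                embed_slice_mask(volume_mask, axis, step.index, step.mask2d)
            if keep_traces:
                traces.append(trace)

    return InstanceMask3D(volume_mask, prompt=p, traces=traces)


def write_traces_csv(traces: list[PropagationTrace], path: str | Path) -> None:
    """Debug export: per-direction propagation tables as one CSV."""
    fields = ["axis", "direction", "slice", "mask_area", "iou_with_prev",
              "stop_reason"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        for trace in traces:
            for row in trace.to_rows():
                w.writerow(row)
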