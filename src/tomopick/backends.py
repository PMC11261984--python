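"""Promptable-segmenter and feature-encoder backends.

The pipeline is backend-agnostic: any object satisfying the
:class:`Segmenter` / :class:`Encoder` protocols can drive it. Two kinds
of backends are provided:

* **Mock backends** — deterministic, dependency-free reference backends
  built from classical image operations (robust thresholding + region
  growing; patch statistics + a band-pass filter bank). They make every
  algorithmic stage of the pipeline testable on synthetic volumes.
* **Foundation-model adapters** — thin wrappers around a promptable
  segmentation model (SAM-style) and a self-supervised ViT encoder
  (DINO-style). These require ``torch`` plus the respective model
  packages and checkpoint files, none of which are bundled; they are
  optional plug-ins behind the same two operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from .core_volume import Image2D

# 4-connectivity in 2D
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class BackendError(ValueError):
    """Raised on invalid prompts or unavailable backends."""


@dataclass
class SegmentationResult:
    """Output of one promptable 2D segmentation call.

    ``peak`` is the (row, col) attaining the maximum of ``confidence``;
    ties are broken lexicographically (smallest row, then column), which
    is what ``np.argmax`` on a C-ordered array returns.
    """

    mask2d: np.ndarray          # bool, same shape as the input image
    confidence: np.ndarray      # float, same shape; finite everywhere
    peak: tuple[int, int]

    @property
    def is_empty(self) -> bool:
        return not self.mask2d.any()


@dataclass
class FeatureMap2D:
    """A grid of feature vectors at reduced resolution.

    shape (h, w, C) with h = ceil(rows / stride), w = ceil(cols / stride).
    """

    data: np.ndarray
    stride: int


@runtime_checkable
class Segmenter(Protocol):
    def segment(self, img: Image2D, point: Optional[tuple[int, int]] = None,
                mask_prompt: Optional[np.ndarray] = None
                ) -> SegmentationResult: ...


@runtime_checkable
class Encoder(Protocol):
    stride: int
    n_channels: int

    def encode(self, img: Image2D) -> FeatureMap2D: ...


def _result_from_mask(mask: np.ndarray) -> SegmentationResult:
    if mask.any():
        dist = ndimage.distance_transform_edt(mask)
        conf = dist / dist.max()
    else:
        conf = np.zeros(mask.shape, dtype=np.float64)
    peak = np.unravel_index(int(np.argmax(conf)), conf.shape)
    return SegmentationResult(mask, conf, (int(peak[0]), int(peak[1])))


@dataclass
class MockSegmenter:
    """Deterministic promptable segmenter for bright-on-dark objects.

    Thresholds the slice at ``background median + k_mad * MAD`` and grows
    a 4-connected region from the prompt point within the above-threshold
    set. A point that itself falls below threshold (a noise dip inside a
    particle) is snapped to the nearest above-threshold pixel within
    ``snap_radius``; beyond that the result is empty — promptable
    segmenters tolerate slightly imprecise points, and a brittle
    single-pixel seed would make the mock fail on prompts that are
    plainly inside an object. With only a mask prompt, the seed is the
    mask centroid snapped to the nearest above-threshold pixel
    (unbounded), and the grown component must overlap the mask prompt.
    On a noiseless slice (MAD = 0) the threshold falls back to halfway
    between the median and the maximum, i.e. the half-maximum contour of
    an isolated object.

    Confidence is the normalized Euclidean distance to the mask boundary
    (0 outside), so the peak is a stable interior point.
    """

    k_mad: float = 3.0
    snap_radius: float = 2.0

    def _threshold(self, p: np.ndarray) -> float:
        med = float(np.median(p))
        mad = float(np.median(np.abs(p - med)))
        if mad > 0:
            return med + self.k_mad * mad
        return med + 0.5 * (float(p.max()) - med)

    def segment(self, img: Image2D, point: Optional[tuple[int, int]] = None,
                mask_prompt: Optional[np.ndarray] = None
                ) -> SegmentationResult:
        if point is None and mask_prompt is None:
            raise BackendError("at least one of point, mask_prompt required")
        p = np.asarray(img.pixels, dtype=np.float64)
        if mask_prompt is not None and mask_prompt.shape != p.shape:
            raise BackendError("mask_prompt shape does not match image")
        empty = _result_from_mask(np.zeros(p.shape, dtype=bool))

        thr = self._threshold(p)
        above = p > thr
        if not above.any():
            return empty

        if point is not None:
            r, c = int(point[0]), int(point[1])
            if not (0 <= r < p.shape[0] and 0 <= c < p.shape[1]):
                raise BackendError(f"point {point} outside image {p.shape}")
            if above[r, c]:
                seed = (r, c)
            else:
                ar, ac = np.nonzero(above)
                d2 = (ar - r) ** 2 + (ac - c) ** 2
                j = int(np.argmin(d2))
                if d2[j] > self.snap_radius**2:
                    return empty
                seed = (int(ar[j]), int(ac[j]))
        else:
            mp = mask_prompt.astype(bool)
            if not mp.any():
                return empty
            rows, cols = np.nonzero(mp)
            cr, cc = rows.mean(), cols.mean()
            ar, ac = np.nonzero(above)
            j = int(np.argmin((ar - cr) ** 2 + (ac - cc) ** 2))
            seed = (int(ar[j]), int(ac[j]))

        labels, _ = ndimage.label(above, structure=_CROSS)
        mask = labels == labels[seed]
        if point is None and not (mask & mask_prompt.astype(bool)).any():
            return empty
        return _result_from_mask(mask)


def _block_mean_2d(a: np.ndarray, stride: int) -> np.ndarray:
    """Mean over stride x stride patches; edge patches average their
    partial extent."""
    r_idx = np.arange(0, a.shape[0], stride)
    c_idx = np.arange(0, a.shape[1], stride)
    s = np.add.reduceat(np.add.reduceat(a, r_idx, axis=0), c_idx, axis=1)
    rc = np.minimum(r_idx + stride, a.shape[0]) - r_idx
    cc = np.minimum(c_idx + stride, a.shape[1]) - c_idx
    return s / np.outer(rc, cc)


def _dog(a: np.ndarray, s1: float, s2: float) -> np.ndarray:
    return ndimage.gaussian_filter(a, s1) - ndimage.gaussian_filter(a, s2)


@dataclass
class MockEncoder:
    """Patch-statistics feature encoder.

    Channels, computed per stride x stride patch of the input slice
    (expected normalized to [0, 1]):

    0. mean of the median-centered, lightly smoothed slice;
    1. standard deviation within the patch (of the smoothed slice);
    2. mean gradient magnitude (of the smoothed slice);
    3+. an oriented band-pass bank, fine to coarse: for each band, the
        slice is difference-of-Gaussians filtered (narrow bands, sigma
        ratio 1.5, center wavelengths 4, 8, 16, 32 px) and the channel
        is the patch-mean *difference* between the squared +45 and -45
        degree diagonal-derivative responses of the band-passed image.
        These channels are signed and orientation/frequency selective:
        isotropic content — broadband noise, the roughly circular
        outlines of particles — cancels in expectation, while an
        oriented texture drives the channel of its frequency band
        positive or negative depending on its in-plane orientation.
        They are the statistics that let two equally bright blobby
        objects point in genuinely different feature directions.

    The std and grad channels are *noise-floor subtracted* (per-slice
    median of the patch-pooled statistic, which a mostly-background
    slice pins to the background noise response) and the mean channel is
    median-centered. Featureless background therefore maps to a
    near-zero vector, which keeps cosine similarity from being dominated
    by shared brightness, and means a coarse pyramid cell only partially
    covered by a particle still points in the particle's feature
    direction.

    ``channel_gains`` rebalance the channels' dynamic ranges (oriented
    band responses are numerically much smaller than patch means) so
    every statistic contributes to cosine similarity. ``n_channels``
    >= 3 selects a prefix of the channel list.
    """

    stride: int = 8
    n_channels: int = 5
    smooth_sigma: float = 1.0
    #: DoG pairs (s, 1.5 s) peak near wavelength s / 0.175: 4, 8, 16, 32 px
    dog_sigmas: tuple[tuple[float, float], ...] = (
        (0.70, 1.05), (1.40, 2.10), (2.80, 4.20), (5.59, 8.39),
    )
    channel_gains: tuple[float, ...] = (1.0, 2.0, 2.0)
    oriented_gain: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_channels < 3:
            raise BackendError("mock encoder needs n_channels >= 3")
        if self.n_channels - 3 > len(self.dog_sigmas):
            raise BackendError(
                f"n_channels={self.n_channels} exceeds available band-pass "
                f"channels ({3 + len(self.dog_sigmas)} max)"
            )

    def encode(self, img: Image2D) -> FeatureMap2D:
        p = np.asarray(img.pixels, dtype=np.float64)
        sm = ndimage.gaussian_filter(p, self.smooth_sigma)
        centered = sm - np.median(sm)

        mean_ch = _block_mean_2d(centered, self.stride)
        m1 = _block_mean_2d(sm, self.stride)
        m2 = _block_mean_2d(sm * sm, self.stride)
        std_ch = np.sqrt(np.maximum(m2 - m1 * m1, 0.0))
        std_ch = std_ch - np.median(std_ch)
        gy, gx = np.gradient(sm)
        grad_ch = _block_mean_2d(np.hypot(gy, gx), self.stride)
        grad_ch = grad_ch - np.median(grad_ch)

        chans = [mean_ch * self.channel_gains[0],
                 std_ch * self.channel_gains[1],
                 grad_ch * self.channel_gains[2]]
        for s1, s2 in self.dog_sigmas[: self.n_channels - 3]:
            band = _dog(p, s1, s2)
            # central differences along the two image diagonals
            d45 = band[2:, 2:] - band[:-2, :-2]
            d135 = band[2:, :-2] - band[:-2, 2:]
            contrast = np.zeros_like(p)
            contrast[1:-1, 1:-1] = d45 * d45 - d135 * d135
            chans.append(
                _block_mean_2d(contrast, self.stride) * self.oriented_gain
            )
        return FeatureMap2D(np.stack(chans, axis=-1), self.stride)


# ---------------------------------------------------------------------------
# Foundation-model adapters (optional; require torch + model packages)
# ---------------------------------------------------------------------------

@dataclass
class FoundationSegmenter:
    """Adapter for a SAM-style promptable segmentation model.

    Loads a checkpoint by path. Confidence is the upsampled mask logit
    map; when the model returns several mask hypotheses the
    highest-scoring one is kept. Requires ``torch`` and
    ``segment_anything``.
    """

    checkpoint: str = ""
    model_type: str = "vit_h"

    def __post_init__(self) -> None:
        try:
            import torch  # noqa: F401
            import segment_anything  # noqa: F401
        except ImportError as e:  # pragma: no cover - optional dependency
            raise BackendError(
                "foundation segmenter requires torch and segment_anything; "
                "install them and provide a checkpoint path"
            ) from e

    def segment(self, img, point=None, mask_prompt=None):  # pragma: no cover
        raise NotImplementedError(
            "foundation segmenter adapter: wire up SamPredictor here"
        )


@dataclass
class FoundationEncoder:
    """Adapter for a self-supervised ViT feature encoder (DINO-style)."""

    checkpoint: str = ""
    stride: int = 14
    n_channels: int = 1024

    def __post_init__(self) -> None:
        try:
            import torch  # noqa: F401
        except ImportError as e:  # pragma: no cover - optional dependency
            raise BackendError(
                "foundation encoder requires torch; install it and provide "
                "a checkpoint path"
            ) from e

    def encode(self, img):  # pragma: no cover
        raise NotImplementedError(
            "foundation encoder adapter: wire up the ViT forward pass here"
        )


def get_segmenter(name: str, **kwargs) -> Segmenter:
    if name == "mock":
        return MockSegmenter(**kwargs)
    if name == "foundation":
        return FoundationSegmenter(**kwargs)
    raise BackendError(f"unknown segmenter backend {name!r}")


def get_encoder(name: str, **kwargs) -> Encoder:
    if name == "mock":
        return MockEncoder(**kwargs)
    if name == "foundation":
        return FoundationEncoder(**kwargs)
    raise BackendError(f"unknown encoder backend {name!r}")
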