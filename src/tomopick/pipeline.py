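"""End-to-end orchestration: one prompt in, a full semantic mask out.

The five stages of a semantic run:

1. encode all three orthogonal views and build the feature pyramid;
2. segment each user prompt into a 3D instance mask (cross-plane
   self-prompting);
3. pool the prompted masks' features into the query vector;
4. hierarchical feature matching + NMS -> top-K point proposals;
5. re-run prompt-based 3D segmentation at every proposal and union the
   retained instance masks (plus the prompted ones) into the semantic
   mask.

Everything downstream of the backends is deterministic; randomness only
exists in synthetic scene generation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .backends import Encoder, Segmenter, get_encoder, get_segmenter
from .core_volume import PointPrompt, Tomogram, VolumeError
from .cross_plane import InstanceMask3D, segment_from_point
from .features import build_pyramid, encode_tomogram
from .matching import (
    ProposalSet,
    QueryFeature,
    hierarchical_match,
    masked_average_pool,
    nms_top_k,
)


class PipelineError(RuntimeError):
    """Raised when a run cannot produce a result."""


@dataclass
class PipelineConfig:
    """All tunables of a run.

    tau_iou : float in [0, 1]
        Stop threshold for cross-plane propagation (adjacent-slice IoU).
    tau_sim : float in [-1, 1]
        Keep threshold on cosine similarity during hierarchical matching.
    k_top : int
        Maximum number of point proposals retained after NMS.
    ratios : decreasing positive ints
        Pyramid downsampling ratios, traversed coarse to fine.
    nms_radius : float or None
        Suppression radius in voxels; None derives it from the prompted
        instance masks (mean bounding-box extent).
    min_instance_fraction : float
        Proposals whose instance mask is smaller than this fraction of
        the mean prompted-instance voxel count are dropped along with
        empty ones — the size filter standard in particle picking, which
        removes one-or-two-voxel noise speckles that a point prompt in
        background can latch onto.
    """

    tau_iou: float = 0.5
    tau_sim: float = 0.5
    k_top: int = 512
    ratios: tuple[int, ...] = (16, 8, 4)
    nms_radius: Optional[float] = None
    min_instance_fraction: float = 0.05
    segmenter: str = "mock"
    encoder: str = "mock"
    norm_percentiles: tuple[float, float] = (1.0, 99.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau_iou <= 1.0:
            raise VolumeError("tau_iou must be in [0, 1]")
        if not -1.0 <= self.tau_sim <= 1.0:
            raise VolumeError("tau_sim must be in [-1, 1]")
        if self.k_top < 1:
            raise VolumeError("k_top must be >= 1")
        self.ratios = tuple(int(r) for r in self.ratios)
        if any(r < 1 for r in self.ratios) or any(
            a <= b for a, b in zip(self.ratios, self.ratios[1:])
        ):
            raise VolumeError("ratios must be positive, strictly decreasing")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["ratios"] = list(self.ratios)
        d["norm_percentiles"] = list(self.norm_percentiles)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "ratios" in d:
            d["ratios"] = tuple(d["ratios"])
        if "norm_percentiles" in d:
            d["norm_percentiles"] = tuple(d["norm_percentiles"])
        return cls(**d)


@dataclass
class RunLog:
    """Structured per-run record (JSON-lines serializable)."""

    events: list[dict] = field(default_factory=list)

    def add(self, stage: str, **info) -> None:
        self.events.append({"stage": stage, **info})

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e) + "\n")

    def get(self, stage: str) -> dict:
        for e in self.events:
            if e["stage"] == stage:
                return e
        raise KeyError(stage)


@dataclass
class SemanticResult:
    semantic_mask: np.ndarray                    # bool (D, H, W)
    instances: list[InstanceMask3D]              # one per retained proposal
    prompted_instances: list[InstanceMask3D]
    proposals: ProposalSet                       # retained proposals only
    query: QueryFeature
    log: RunLog

    def pick_coordinates(self, mode: str = "proposal") -> np.ndarray:
        """Pick centers for evaluation: the proposal coordinates
        themselves (default) or each retained instance mask's centroid."""
        if mode == "proposal":
            return self.proposals.coordinates()
        if mode == "centroid":
            if not self.instances:
                return np.empty((0, 3), dtype=float)
            return np.array([
                np.argwhere(inst.data).mean(axis=0) for inst in self.instances
            ])
        raise ValueError(f"unknown pick-center mode {mode!r}")


def run_instance(t: Tomogram, p: PointPrompt, cfg: PipelineConfig,
                 segmenter: Optional[Segmenter] = None) -> InstanceMask3D:
    """Segment a single prompted particle into a 3D instance mask."""
    seg = segmenter if segmenter is not None else get_segmenter(cfg.segmenter)
    return segment_from_point(
        t, p, seg, tau_iou=cfg.tau_iou,
        norm_percentiles=cfg.norm_percentiles,
    )


def _auto_nms_radius(masks: Sequence[InstanceMask3D]) -> float:
    """Mean bounding-box extent of the prompted instances: ties the
    suppression scale to the actual particle size."""
    extents = []
    for m in masks:
        bb = m.bounding_box_extents()
        if bb is not None:
            extents.append(float(np.mean(bb)))
    if not extents:
        raise PipelineError("cannot derive NMS radius: all masks empty")
    return float(np.mean(extents))


def run_semantic(t: Tomogram, prompts: Sequence[PointPrompt],
                 cfg: PipelineConfig) -> SemanticResult:
    """Segment every particle of the prompted category in the tomogram."""
    if not prompts:
        raise PipelineError("at least one prompt required")
    segmenter = get_segmenter(cfg.segmenter)
    encoder: Encoder = get_encoder(cfg.encoder)
    log = RunLog()

    t0 = time.perf_counter()
    fvol = encode_tomogram(t, encoder, cfg.norm_percentiles)
    pyramid = build_pyramid(fvol, cfg.ratios)
    log.add("encode", elapsed_s=time.perf_counter() - t0,
            channels=fvol.data.shape[3],
            pyramid_shapes=[list(l.grid_shape) for l in pyramid])

    t0 = time.perf_counter()
    prompted = []
    for p in prompts:
        inst = run_instance(t, p, cfg, segmenter)
        if inst.is_empty:
            log.add("empty_instance", prompt=list(p.as_tuple()))
        else:
            prompted.append(inst)
    if not prompted:
        raise PipelineError(
            "no query support: every prompt produced an empty instance mask"
        )
    log.add("prompted_instances", elapsed_s=time.perf_counter() - t0,
            n_prompts=len(prompts), n_nonempty=len(prompted),
            voxels=[m.count() for m in prompted])

    query = masked_average_pool(fvol, prompted)
    log.add("query", n_voxels=query.n_voxels)

    t0 = time.perf_counter()
    finest, n_eval = hierarchical_match(pyramid, query, cfg.tau_sim)
    finest_cells = int(np.prod(finest.scores.shape))
    radius = cfg.nms_radius if cfg.nms_radius is not None \
        else _auto_nms_radius(prompted)
    proposals = nms_top_k(finest, cfg.tau_sim, radius, cfg.k_top)
    log.add("matching", elapsed_s=time.perf_counter() - t0,
            cosine_evaluations=n_eval, finest_cells=finest_cells,
            eval_fraction=n_eval / finest_cells,
            nms_radius=radius, n_proposals=len(proposals))

    t0 = time.perf_counter()
    semantic = np.zeros(t.shape, dtype=bool)
    for m in prompted:
        semantic |= m.data
    min_voxels = max(1.0, cfg.min_instance_fraction
                     * float(np.mean([m.count() for m in prompted])))
    instances: list[InstanceMask3D] = []
    retained: list[tuple[int, int, int, float]] = []
    for z, y, x, score in proposals.points:
        inst = run_instance(t, PointPrompt(z, y, x), cfg, segmenter)
        if inst.count() < min_voxels:
            continue
        instances.append(inst)
        retained.append((z, y, x, score))
        semantic |= inst.data
    log.add("proposal_instances", elapsed_s=time.perf_counter() - t0,
            n_retained=len(retained), min_instance_voxels=min_voxels,
            n_dropped_small=len(proposals) - len(retained))

    return SemanticResult(
        semantic_mask=semantic,
        instances=instances,
        prompted_instances=prompted,
        proposals=ProposalSet(retained),
        query=query,
        log=log,
    )
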