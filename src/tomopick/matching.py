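"""Hierarchical feature matching: query pooling, coarse-to-fine cosine
similarity with keep-mask propagation, NMS, and top-K point proposals.

The query vector is the masked average of full-resolution features over
the prompted instance masks. Matching starts at the coarsest pyramid
level, evaluates cosine similarity for every cell, keeps cells scoring
at least ``tau_sim``, and propagates the keep-mask to the next finer
level by nearest-neighbor upsampling, so finer levels only evaluate
descendants of kept coarse cells. A naive full-resolution matcher is
provided as the reference baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_volume import VolumeError
from .features import FeaturePyramidLevel, FeatureVolume

logger = logging.getLogger(__name__)


class MatchingError(ValueError):
    """Raised on degenerate queries or inconsistent levels."""


@dataclass
class QueryFeature:
    """MAP-pooled feature vector representing the prompted category."""

    vector: np.ndarray
    n_voxels: int          # total nonzero count over all contributing masks

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if self.n_voxels < 1:
            raise MatchingError("query needs at least one contributing voxel")
        if not np.all(np.isfinite(self.vector)):
            raise MatchingError("query vector has non-finite entries")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vector))


@dataclass
class SimilarityLevel:
    """Cosine scores at one pyramid level.

    ``scores`` holds cosine values on evaluated cells and 0 elsewhere;
    ``evaluated`` marks which cells were actually computed (cells pruned
    by the propagated keep-mask stay unevaluated).
    """

    ratio: int
    scores: np.ndarray          # float64 grid
    evaluated: np.ndarray       # bool grid
    full_shape: tuple[int, int, int]

    def keep_mask(self, tau_sim: float) -> np.ndarray:
        return self.evaluated & (self.scores >= tau_sim)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lvl = FeaturePyramidLevel(self.ratio, self.scores[..., None],
                                  self.full_shape)
        return lvl.cell_centers()


@dataclass
class ProposalSet:
    """Scored point prompts in full-resolution voxel coordinates,
    descending by score, pairwise at least the NMS radius apart."""

    points: list[tuple[int, int, int, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def coordinates(self) -> np.ndarray:
        return np.array([p[:3] for p in self.points], dtype=int).reshape(-1, 3)

    def scores(self) -> np.ndarray:
        return np.array([p[3] for p in self.points], dtype=float)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write("z,y,x,score\n")
            for z, y, x, s in self.points:
                fh.write(f"{z},{y},{x},{s:.9f}\n")


# ---------------------------------------------------------------------------
# Query construction
# ---------------------------------------------------------------------------

def masked_average_pool(f: FeatureVolume, masks: Sequence) -> QueryFeature:
    """Average the full-resolution feature vectors over instance masks.

    The denominator is the sum of each mask's nonzero count, so a voxel
    covered by several prompted instances contributes once per mask.
    Raises :class:`MatchingError` when every mask is empty.
    """
    total = np.zeros(f.data.shape[3], dtype=np.float64)
    count = 0
    for m in masks:
        mask = np.asarray(m) if isinstance(m, np.ndarray) else m.data
        if mask.shape != f.grid_shape:
            raise VolumeError(
                f"mask shape {mask.shape} != volume {f.grid_shape}"
            )
        mask = mask.astype(bool)
        n = int(np.count_nonzero(mask))
        if n == 0:
            continue
        total += f.data[mask].sum(axis=0, dtype=np.float64)
        count += n
    if count == 0:
        raise MatchingError("all masks empty: no voxels to pool")
    return QueryFeature(total / count, count)


# ---------------------------------------------------------------------------
# Cosine similarity
# ---------------------------------------------------------------------------

def _cosine_rows(cells: np.ndarray, q: np.ndarray, q_norm: float
                 ) -> np.ndarray:
    """Cosine between each row of ``cells`` and ``q``; zero rows score 0.

    Uses an explicit multiply-sum so the per-row reduction order is
    independent of how many rows are evaluated (subset evaluation is
    bit-identical to full evaluation).
    """
    cells = cells.astype(np.float64, copy=False)
    dots = (cells * q).sum(axis=1)
    norms = np.sqrt((cells * cells).sum(axis=1))
    out = np.zeros(cells.shape[0], dtype=np.float64)
    nz = norms > 0
    out[nz] = dots[nz] / (norms[nz] * q_norm)
    return out


def cosine_similarity_level(q: QueryFeature, level: FeaturePyramidLevel,
                            evaluate_mask: Optional[np.ndarray] = None
                            ) -> SimilarityLevel:
    """Point-wise cosine similarity of a pyramid level against the query.

    Only cells of ``evaluate_mask`` are computed when given; cells whose
    feature vector is exactly zero score 0 by convention (featureless
    background is legitimate, not an error).
    """
    if q.norm == 0:
        raise MatchingError("zero query vector cannot be cosine-matched")
    grid = level.data
    shape = grid.shape[:3]
    scores = np.zeros(shape, dtype=np.float64)
    if evaluate_mask is None:
        evaluated = np.ones(shape, dtype=bool)
        scores[evaluated] = _cosine_rows(
            grid.reshape(-1, grid.shape[3]), q.vector, q.norm
        )
    else:
        if evaluate_mask.shape != shape:
            raise VolumeError("evaluate_mask shape mismatch")
        evaluated = evaluate_mask.astype(bool)
        if evaluated.any():
            scores[evaluated] = _cosine_rows(
                grid[evaluated], q.vector, q.norm
            )
    return SimilarityLevel(level.ratio, scores, evaluated, level.full_shape)


def propagate_keep_mask(keep: np.ndarray, ratio: int, next_ratio: int,
                        next_shape: tuple[int, ...]) -> np.ndarray:
    """Nearest-neighbor upsample a keep-mask to the next finer level.

    A cell at the finer ratio is evaluable iff its containing coarse
    cell was kept; ``next_ratio`` must divide ``ratio``.
    """
    if ratio % next_ratio != 0:
        raise MatchingError(
            f"next ratio {next_ratio} must divide coarse ratio {ratio}"
        )
    f = ratio // next_ratio
    out = keep
    for ax in range(3):
        out = np.repeat(out, f, axis=ax)
    return out[: next_shape[0], : next_shape[1], : next_shape[2]]


def hierarchical_match(levels: Sequence[FeaturePyramidLevel],
                       q: QueryFeature, tau_sim: float
                       ) -> tuple[SimilarityLevel, int]:
    """Match the query coarse-to-fine; returns the finest level's
    similarity and the total number of cosine evaluations performed.

    All cells of the coarsest level are evaluated; each subsequent level
    only evaluates cells whose coarse ancestor passed ``tau_sim``. If
    nothing at the coarsest level passes, the single best-scoring coarse
    cell is kept as a fallback so one proposal chain survives.
    """
    if not levels:
        raise MatchingError("empty pyramid")
    n_eval = 0
    evaluate_mask: Optional[np.ndarray] = None
    sim: Optional[SimilarityLevel] = None
    for i, level in enumerate(levels):
        sim = cosine_similarity_level(q, level, evaluate_mask)
        n_eval += int(np.count_nonzero(sim.evaluated))
        if i + 1 == len(levels):
            break
        keep = sim.keep_mask(tau_sim)
        if i == 0 and not keep.any():
            best = np.unravel_index(int(np.argmax(sim.scores)), sim.scores.shape)
            keep = np.zeros_like(keep)
            keep[best] = True
            logger.warning(
                "coarsest keep-mask empty (max score %.3f < tau_sim %.3f); "
                "falling back to the single best cell %s",
                float(sim.scores.max()), tau_sim, best,
            )
        evaluate_mask = propagate_keep_mask(
            keep, level.ratio, levels[i + 1].ratio,
            levels[i + 1].grid_shape,
        )
    assert sim is not None
    return sim, n_eval


def naive_match(f: FeatureVolume, q: QueryFeature) -> np.ndarray:
    """Cosine similarity at every full-resolution voxel (the brute-force
    baseline hierarchical matching is measured against)."""
    if q.norm == 0:
        raise MatchingError("zero query vector cannot be cosine-matched")
    flat = f.data.reshape(-1, f.data.shape[3])
    return _cosine_rows(flat, q.vector, q.norm).reshape(f.grid_shape)


# ---------------------------------------------------------------------------
# NMS + top-K
# ---------------------------------------------------------------------------

def nms_top_k(sim: SimilarityLevel, tau_sim: float, radius: float, k: int
              ) -> ProposalSet:
    """Greedy non-maximum suppression over kept cells, capped at K.

    Cells passing ``tau_sim`` are visited by descending score (ties
    broken by lexicographic cell coordinate); a cell is accepted iff its
    full-resolution center is at least ``radius`` (Euclidean, voxels)
    from every previously accepted center.
    """
    if radius <= 0:
        raise MatchingError("NMS radius must be positive")
    if k < 1:
        raise MatchingError("K must be >= 1")
    keep = sim.keep_mask(tau_sim)
    if not keep.any():
        return ProposalSet()
    cz, cy, cx = np.nonzero(keep)
    scores = sim.scores[cz, cy, cx]
    order = np.lexsort((cx, cy, cz, -scores))
    centers_axes = sim.cell_centers()
    pts = np.stack(
        [centers_axes[0][cz], centers_axes[1][cy], centers_axes[2][cx]],
        axis=1,
    ).astype(float)

    accepted: list[int] = []
    acc_pts = np.empty((0, 3))
    r2 = radius * radius
    for j in order:
        if accepted:
            d2 = ((acc_pts - pts[j]) ** 2).sum(axis=1)
            if (d2 < r2).any():
                continue
        accepted.append(int(j))
        acc_pts = np.vstack([acc_pts, pts[j]])
        if len(accepted) >= k:
            break
    points = [
        (int(pts[j, 0]), int(pts[j, 1]), int(pts[j, 2]), float(scores[j]))
        for j in accepted
    ]
    return ProposalSet(points)
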