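import itertools

import numpy as np
import pytest

from tomopick import (
    build_pyramid,
    cosine_similarity_level,
    hierarchical_match,
    masked_average_pool,
    naive_match,
    nms_top_k,
    propagate_keep_mask,
)
from tomopick.features import FeaturePyramidLevel, FeatureVolume
from tomopick.matching import MatchingError, QueryFeature, SimilarityLevel


def fv(data):
    data = np.asarray(data, dtype=float)
    return FeatureVolume(data, data.shape[-1] // 3)


def sim_from_scores(scores, ratio=1, full_shape=None):
    scores = np.asarray(scores, dtype=float)
    return SimilarityLevel(ratio, scores, np.ones(scores.shape, bool),
                           full_shape or scores.shape)


class TestMaskedAveragePool:
    def test_single_voxel_mask_returns_its_vector(self):
        rng = np.random.default_rng(0)
        f = fv(rng.normal(size=(3, 3, 3, 3)))
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 2, 0] = True
        q = masked_average_pool(f, [m])
        assert np.allclose(q.vector, f.data[1, 2, 0])
        assert q.n_voxels == 1

    def test_constant_field_returns_constant(self):
        f = fv(np.full((4, 4, 4, 3), 1.25))
        m = np.zeros((4, 4, 4), dtype=bool)
        m[:2] = True
        q = masked_average_pool(f, [m])
        assert np.allclose(q.vector, 1.25)

    def test_two_single_voxel_masks_average(self):
        data = np.zeros((2, 1, 1, 3))
        data[0, 0, 0] = [1, 0, 0]
        data[1, 0, 0] = [0, 1, 0]
        f = fv(data)
        m0 = np.zeros((2, 1, 1), bool)
        m0[0] = True
        m1 = np.zeros((2, 1, 1), bool)
        m1[1] = True
        q = masked_average_pool(f, [m0, m1])
        assert np.allclose(q.vector, [0.5, 0.5, 0.0])
        assert q.n_voxels == 2

    def test_overlapping_masks_count_per_mask(self):
        # a voxel present in both masks contributes twice to numerator
        # and denominator
        data = np.zeros((2, 1, 1, 3))
        data[0, 0, 0] = [3, 0, 0]
        data[1, 0, 0] = [0, 3, 0]
        f = fv(data)
        m0 = np.ones((2, 1, 1), bool)     # both voxels
        m1 = np.zeros((2, 1, 1), bool)
        m1[0] = True                       # voxel 0 again
        q = masked_average_pool(f, [m0, m1])
        assert q.n_voxels == 3
        assert np.allclose(q.vector, [2.0, 1.0, 0.0])

    def test_all_masks_empty(self):
        f = fv(np.zeros((2, 2, 2, 3)))
        with pytest.raises(MatchingError, match="empty"):
            masked_average_pool(f, [np.zeros((2, 2, 2), bool)])


class TestCosineSimilarity:
    def _level(self, data, ratio=1):
        data = np.asarray(data, dtype=float)
        return FeaturePyramidLevel(ratio, data, data.shape[:3])

    def test_equal_vector_scores_one(self):
        lvl = self._level(np.full((1, 1, 1, 3), 2.0))
        q = QueryFeature(np.array([2.0, 2.0, 2.0]), 1)
        s = cosine_similarity_level(q, lvl)
        assert s.scores[0, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_scores_zero(self):
        data = np.zeros((1, 1, 1, 3))
        data[0, 0, 0] = [0, 1, 0]
        q = QueryFeature(np.array([1.0, 0.0, 0.0]), 1)
        s = cosine_similarity_level(q, self._level(data))
        assert s.scores[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_analytic_inverse_sqrt2(self):
        data = np.zeros((1, 1, 1, 3))
        data[0, 0, 0] = [1, 0, 0]
        q = QueryFeature(np.array([1.0, 1.0, 0.0]), 1)
        s = cosine_similarity_level(q, self._level(data))
        assert s.scores[0, 0, 0] == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_zero_feature_cell_scores_zero(self):
        data = np.zeros((2, 1, 1, 3))
        data[0, 0, 0] = [1, 0, 0]
        q = QueryFeature(np.array([1.0, 0.0, 0.0]), 1)
        s = cosine_similarity_level(q, self._level(data))
        assert s.scores[1, 0, 0] == 0.0

    def test_zero_query_rejected(self):
        with pytest.raises(MatchingError, match="zero query"):
            cosine_similarity_level(QueryFeature(np.zeros(3), 1),
                                    self._level(np.ones((1, 1, 1, 3))))

    def test_evaluate_mask_restricts_cells(self):
        rng = np.random.default_rng(1)
        lvl = self._level(rng.normal(size=(3, 3, 3, 3)))
        q = QueryFeature(np.array([1.0, 0.5, -0.5]), 1)
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[2, 2, 2] = True
        s = cosine_similarity_level(q, lvl, mask)
        assert s.evaluated.sum() == 2
        assert s.scores[1, 1, 1] == 0.0
        full = cosine_similarity_level(q, lvl)
        assert s.scores[0, 0, 0] == full.scores[0, 0, 0]


class TestPropagateKeepMask:
    def test_all_true_propagates_all_true(self):
        keep = np.ones((2, 2, 2), bool)
        out = propagate_keep_mask(keep, 8, 4, (4, 4, 4))
        assert out.all() and out.shape == (4, 4, 4)

    def test_single_cell_has_exactly_eight_children(self):
        keep = np.zeros((2, 2, 2), bool)
        keep[1, 0, 1] = True
        out = propagate_keep_mask(keep, 16, 8, (4, 4, 4))
        assert out.sum() == 8
        assert out[2:4, 0:2, 2:4].all()

    def test_empty_propagates_empty(self):
        out = propagate_keep_mask(np.zeros((2, 2, 2), bool), 8, 4, (4, 4, 4))
        assert not out.any()

    def test_crops_to_next_shape(self):
        keep = np.ones((2, 2, 2), bool)
        out = propagate_keep_mask(keep, 8, 4, (3, 4, 3))
        assert out.shape == (3, 4, 3)

    def test_non_divisible_ratio_rejected(self):
        with pytest.raises(MatchingError, match="divide"):
            propagate_keep_mask(np.ones((2, 2, 2), bool), 8, 3, (6, 6, 6))


class TestHierarchicalMatch:
    def test_field_equal_to_query_scores_one_everywhere(self):
        f = fv(np.ones((8, 8, 8, 3)))
        q = QueryFeature(np.ones(3), 1)
        levels = build_pyramid(f, (4, 2))
        sim, n_eval = hierarchical_match(levels, q, tau_sim=0.5)
        assert np.allclose(sim.scores, 1.0)
        assert sim.evaluated.all()
        assert n_eval == 2**3 + 4**3

    def test_tau_disabled_equals_full_evaluation_bitwise(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            shape = tuple(rng.integers(9, 33, size=3))
            f = fv(rng.normal(size=(*shape, 6)).astype(np.float32))
            q = QueryFeature(rng.normal(size=6), 1)
            levels = build_pyramid(f, (8, 4, 2))
            sim, _ = hierarchical_match(levels, q, tau_sim=-1.0)
            full = cosine_similarity_level(q, levels[-1])
            assert np.array_equal(sim.scores, full.scores)

    def test_ratio_one_equals_naive_bitwise(self):
        rng = np.random.default_rng(5)
        f = fv(rng.normal(size=(12, 10, 14, 6)).astype(np.float32))
        q = QueryFeature(rng.normal(size=6), 1)
        (lvl,) = build_pyramid(f, (1,))
        sim, n_eval = hierarchical_match([lvl], q, tau_sim=-1.0)
        assert np.array_equal(sim.scores, naive_match(f, q))
        assert n_eval == 12 * 10 * 14

    def test_planted_block_wins_argmax(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(32, 32, 32, 6)) * 0.05
        data[8:16, 16:24, 8:16] = [1, 1, 0, 0, 1, 0]
        f = fv(data)
        q = QueryFeature(np.array([1.0, 1, 0, 0, 1, 0]), 1)
        levels = build_pyramid(f, (8, 4, 2))
        sim, n_eval = hierarchical_match(levels, q, tau_sim=0.5)
        # oracle: evaluate every finest-level cell directly
        full = cosine_similarity_level(q, levels[-1])
        best = np.unravel_index(np.argmax(np.where(sim.evaluated, sim.scores,
                                                   -2.0)), sim.scores.shape)
        oracle_best = np.unravel_index(np.argmax(full.scores),
                                       full.scores.shape)
        assert best == oracle_best
        assert 4 <= best[0] < 8 and 8 <= best[1] < 12 and 4 <= best[2] < 8
        assert n_eval < full.scores.size + 4**3 + 8**3  # filtering active

    def test_coarsest_fallback_keeps_best_cell(self):
        # nothing passes tau at the coarsest level: the single best cell
        # is still propagated so one proposal chain survives
        rng = np.random.default_rng(7)
        data = rng.normal(size=(16, 16, 16, 3)) * 0.01
        data[4:8, 4:8, 4:8] = [0.4, 0.4, 0.4]       # weak but best match
        f = fv(data)
        q = QueryFeature(np.array([1.0, 1.0, 1.0]), 1)
        levels = build_pyramid(f, (8, 4))
        sim, _ = hierarchical_match(levels, q, tau_sim=0.99999)
        assert sim.evaluated.sum() == 8   # exactly one coarse cell's children

    def test_empty_levels_rejected(self):
        with pytest.raises(MatchingError, match="empty"):
            hierarchical_match([], QueryFeature(np.ones(3), 1), 0.5)


class TestNaiveMatch:
    def test_constant_field_equal_query(self):
        f = fv(np.ones((4, 4, 4, 3)) * 2)
        assert np.allclose(naive_match(f, QueryFeature(np.ones(3), 1)), 1.0)

    def test_single_matching_voxel_is_unique_max(self):
        data = np.tile([0.0, 1.0, 0.0], (4, 4, 4, 1))
        data[2, 1, 3] = [1, 0, 0]
        f = fv(data)
        s = naive_match(f, QueryFeature(np.array([1.0, 0, 0]), 1))
        assert np.unravel_index(np.argmax(s), s.shape) == (2, 1, 3)
        assert (s == s.max()).sum() == 1


def brute_force_nms(cells, radius, k):
    """Exhaustive suppression oracle: repeatedly take the best remaining
    cell (score desc, coordinate-lexicographic ties) and delete everything
    within the radius."""
    remaining = sorted(cells, key=lambda c: (-c[3], c[0], c[1], c[2]))
    accepted = []
    while remaining and len(accepted) < k:
        best = remaining.pop(0)
        accepted.append(best)
        remaining = [
            c for c in remaining
            if (c[0] - best[0]) ** 2 + (c[1] - best[1]) ** 2
            + (c[2] - best[2]) ** 2 >= radius**2
        ]
    return [(c[0], c[1], c[2], c[3]) for c in accepted]


class TestNmsTopK:
    def test_single_cell(self):
        scores = np.zeros((3, 3, 3))
        scores[1, 1, 1] = 0.9
        sim = sim_from_scores(scores)
        out = nms_top_k(sim, 0.5, radius=2.0, k=5)
        assert out.points == [(1, 1, 1, 0.9)]

    def test_close_pair_suppressed(self):
        scores = np.zeros((1, 1, 4))
        scores[0, 0, 1] = 0.9
        scores[0, 0, 2] = 0.8
        out = nms_top_k(sim_from_scores(scores), 0.5, radius=2.0, k=5)
        assert out.points == [(0, 0, 1, 0.9)]

    def test_matches_brute_force_oracle_on_grid(self):
        rng = np.random.default_rng(8)
        scores = np.round(rng.uniform(0.0, 1.0, size=(1, 5, 5)), 3)
        sim = sim_from_scores(scores)
        out = nms_top_k(sim, 0.5, radius=2.0, k=3)
        cells = [(0, y, x, scores[0, y, x])
                 for y in range(5) for x in range(5)
                 if scores[0, y, x] >= 0.5]
        assert out.points == brute_force_nms(cells, 2.0, 3)

    def test_k_caps_output(self):
        scores = np.linspace(0.5, 1.0, 27).reshape(3, 3, 3)
        out = nms_top_k(sim_from_scores(scores), 0.5, radius=0.5, k=4)
        assert len(out) == 4
        assert list(out.scores()) == sorted(out.scores(), reverse=True)

    def test_empty_input(self):
        out = nms_top_k(sim_from_scores(np.zeros((2, 2, 2))), 0.5, 2.0, 3)
        assert len(out) == 0

    def test_cell_centers_at_coarse_ratio(self):
        scores = np.zeros((2, 2, 2))
        scores[1, 0, 1] = 0.7
        sim = SimilarityLevel(4, scores, np.ones((2, 2, 2), bool), (8, 8, 8))
        out = nms_top_k(sim, 0.5, radius=2.0, k=1)
        assert out.points[0][:3] == (6, 2, 6)

    def test_pairwise_distance_invariant_on_random_fields(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            scores = rng.uniform(-1, 1, size=(6, 6, 6))
            radius = float(rng.uniform(1.0, 4.0))
            out = nms_top_k(sim_from_scores(scores), 0.3, radius, 20)
            pts = out.coordinates().astype(float)
            for i, j in itertools.combinations(range(len(pts)), 2):
                assert np.linalg.norm(pts[i] - pts[j]) >= radius

    def test_parameter_validation(self):
        sim = sim_from_scores(np.zeros((2, 2, 2)))
        with pytest.raises(MatchingError):
            nms_top_k(sim, 0.5, radius=0.0, k=1)
        with pytest.raises(MatchingError):
            nms_top_k(sim, 0.5, radius=1.0, k=0)

    def test_csv_export(self, tmp_path):
        scores = np.zeros((3, 3, 3))
        scores[2, 1, 0] = 0.75
        out = nms_top_k(sim_from_scores(scores), 0.5, 2.0, 3)
        path = tmp_path / "p.csv"
        out.write_csv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "z,y,x,score"
        assert lines[1].startswith("2,1,0,0.75")
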