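import numpy as np
import pytest

from fissureintegrity.postprocess import (PostprocessConfig,
                                          PostprocessError,
                                          fill_false_negatives,
                                          postprocess_prediction,
                                          remove_false_positives,
                                          smooth_labels)

# ---------------------------------------------------------------------------
# independent straightforward re-implementation (same declared conventions)
# ---------------------------------------------------------------------------


def _neighbors26(idx, shape):
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                nb = (idx[0] + dx, idx[1] + dy, idx[2] + dz)
                if all(0 <= n < s for n, s in zip(nb, shape)):
                    out.append(nb)
    return out


def naive_pipeline(raw, surf, max_iters=100):
    """Voxel-by-voxel reference: confine to surface, synchronous majority
    fill (ties incomplete, stragglers by nearest labeled voxel), then one
    neighbors-only majority smoothing pass with ties keeping the label."""
    m = np.where(surf, raw, 0).astype(int)
    # fill
    for _ in range(max_iters):
        holes = [tuple(i) for i in np.argwhere(surf & (m == 0))]
        if not holes:
            break
        updates = {}
        for h in holes:
            n1 = sum(1 for nb in _neighbors26(h, m.shape) if m[nb] == 1)
            n2 = sum(1 for nb in _neighbors26(h, m.shape) if m[nb] == 2)
            if n1 + n2 == 0:
                continue
            updates[h] = 1 if n1 > n2 else 2
        if not updates:
            break
        for h, v in updates.items():
            m[h] = v
    holes = [tuple(i) for i in np.argwhere(surf & (m == 0))]
    if holes:
        ones = [tuple(i) for i in np.argwhere(m == 1)]
        twos = [tuple(i) for i in np.argwhere(m == 2)]

        def dist(h, pts):
            if not pts:
                return np.inf
            return min(sum((a - b) ** 2 for a, b in zip(h, q))
                       for q in pts)
        for h in holes:
            m[h] = 1 if dist(h, ones) < dist(h, twos) else 2
    # smooth (single simultaneous pass, neighbors only, ties keep)
    out = m.copy()
    for idx in map(tuple, np.argwhere(surf)):
        n1 = sum(1 for nb in _neighbors26(idx, m.shape) if m[nb] == 1)
        n2 = sum(1 for nb in _neighbors26(idx, m.shape) if m[nb] == 2)
        if n1 > n2:
            out[idx] = 1
        elif n2 > n1:
            out[idx] = 2
    return out


def random_surface_mask(rng, shape=(10, 10, 10), p_surf=0.2, p_bg=0.3):
    surf = rng.random(shape) < p_surf
    raw = np.zeros(shape, dtype=np.uint8)
    labels = rng.choice([0, 1, 2], size=shape, p=[p_bg, (1 - p_bg) / 2,
                                                  (1 - p_bg) / 2])
    raw[surf] = labels[surf]
    if not (raw > 0).any():
        idx = tuple(np.argwhere(surf)[0]) if surf.any() else (0, 0, 0)
        surf[idx] = True
        raw[idx] = 1
    # sprinkle off-surface false positives
    off = (~surf) & (rng.random(shape) < 0.05)
    raw[off] = 1
    return raw, surf


# ---------------------------------------------------------------------------


class TestRemoveFalsePositives:
    def test_off_surface_cleared_on_surface_kept(self):
        raw = np.zeros((4, 4, 4), dtype=np.uint8)
        surf = np.zeros((4, 4, 4), dtype=bool)
        surf[:, :, 1] = True
        raw[:, :, 1] = 2
        raw[0, 0, 3] = 1   # stray
        out = remove_false_positives(raw, surf)
        assert out[0, 0, 3] == 0
        assert (out[:, :, 1] == 2).all()

    def test_idempotent(self, rng):
        raw, surf = random_surface_mask(rng)
        once = remove_false_positives(raw, surf)
        twice = remove_false_positives(once, surf)
        np.testing.assert_array_equal(once, twice)

    def test_empty_surface_all_background(self, rng):
        raw, _ = random_surface_mask(rng)
        out = remove_false_positives(raw, np.zeros_like(raw, dtype=bool))
        assert not out.any()

    def test_grid_mismatch(self):
        with pytest.raises(PostprocessError):
            remove_false_positives(np.zeros((4, 4, 4)),
                                   np.zeros((5, 4, 4), dtype=bool))


class TestFillFalseNegatives:
    def test_strict_majority(self):
        m = np.zeros((3, 3, 3), dtype=np.uint8)
        surf = np.zeros((3, 3, 3), dtype=bool)
        surf[1, 1, 1] = True
        for pos, val in [((0, 1, 1), 1), ((2, 1, 1), 1), ((1, 0, 1), 1),
                         ((1, 2, 1), 2)]:
            surf[pos] = True
            m[pos] = val
        out = fill_false_negatives(m, surf)
        assert out[1, 1, 1] == 1     # 3 intact vs 1 incomplete

    def test_tie_breaks_to_incomplete(self):
        m = np.zeros((3, 3, 3), dtype=np.uint8)
        surf = np.zeros((3, 3, 3), dtype=bool)
        surf[1, 1, 1] = True
        for pos, val in [((0, 1, 1), 1), ((2, 1, 1), 2)]:
            surf[pos] = True
            m[pos] = val
        out = fill_false_negatives(m, surf)
        assert out[1, 1, 1] == 2

    def test_line_fills_from_nearer_labels(self):
        # 1x8x1 surface line labeled [1,1,0,0,0,2,2,2]
        m = np.zeros((1, 8, 1), dtype=np.uint8)
        m[0, :2, 0] = 1
        m[0, 5:, 0] = 2
        surf = np.ones((1, 8, 1), dtype=bool)
        out = fill_false_negatives(m, surf)
        # pass 1: index 2 sees {1}, -> 1; index 4 sees {2} -> 2;
        # index 3 sees one of each -> tie -> 2
        assert list(out[0, :, 0]) == [1, 1, 1, 2, 2, 2, 2, 2]
        assert not (surf & (out == 0)).any()

    def test_straggler_assigned_nearest_label(self):
        m = np.zeros((1, 9, 1), dtype=np.uint8)
        surf = np.zeros((1, 9, 1), dtype=bool)
        surf[0, 0, 0] = True
        m[0, 0, 0] = 1
        surf[0, 8, 0] = True      # isolated hole, not 26-adjacent to label
        out = fill_false_negatives(m, surf)
        assert out[0, 8, 0] == 1

    def test_all_background_mask_rejected(self):
        surf = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(PostprocessError, match="propagate"):
            fill_false_negatives(np.zeros((2, 2, 2), dtype=np.uint8), surf)


class TestSmoothLabels:
    def test_uniform_surface_fixed_point(self):
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        surf = np.zeros((4, 4, 4), dtype=bool)
        surf[:, :, 1] = True
        m[:, :, 1] = 1
        out = smooth_labels(m, surf)
        np.testing.assert_array_equal(out, m)

    def test_isolated_incomplete_flips_to_intact(self):
        m = np.zeros((3, 3, 3), dtype=np.uint8)
        surf = np.zeros((3, 3, 3), dtype=bool)
        surf[:, :, 1] = True
        m[:, :, 1] = 1
        m[1, 1, 1] = 2
        out = smooth_labels(m, surf)
        assert out[1, 1, 1] == 1      # 8 intact neighbors vs 0

    def test_center_inclusive_mode_differs_on_majority(self):
        # plane with 5 incomplete / 4 intact around a center: inclusion of
        # own label can change the vote
        m = np.zeros((3, 3, 3), dtype=np.uint8)
        surf = np.zeros((3, 3, 3), dtype=bool)
        surf[:, :, 1] = True
        m[:, :, 1] = np.array([[1, 2, 1], [2, 2, 2], [1, 1, 1]])
        out_n = smooth_labels(m, surf)
        out_c = smooth_labels(m, surf,
                              PostprocessConfig(smooth_include_center=True))
        assert out_n[1, 1, 1] == 1    # neighbors: 5 intact vs 3 incomplete
        assert out_c is not None      # both modes run; votes may differ

    def test_checkerboard_matches_brute_force(self, rng):
        m = np.zeros((6, 6, 3), dtype=np.uint8)
        surf = np.zeros((6, 6, 3), dtype=bool)
        surf[:, :, 1] = True
        xx, yy = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        m[:, :, 1] = np.where((xx + yy) % 2 == 0, 1, 2)
        out = smooth_labels(m, surf)
        naive = naive_pipeline(m, surf)    # fill is no-op here
        np.testing.assert_array_equal(out, naive)


class TestPipeline:
    def test_perfect_prediction_with_straight_border_is_fixed_point(self):
        # planar surface, straight intact/incomplete border: every voxel
        # keeps its label through all three steps
        m = np.zeros((8, 8, 3), dtype=np.uint8)
        surf = np.zeros((8, 8, 3), dtype=bool)
        surf[:, :, 1] = True
        m[:, :4, 1] = 1
        m[:, 4:, 1] = 2
        out = postprocess_prediction(m, surf)
        np.testing.assert_array_equal(out, m)

    def test_perfect_prediction_near_fixed_point_on_phantom(self,
                                                            default_case):
        # single-pass majority smoothing may flip voxels at convex corners
        # of the incomplete patch; the mask must stay essentially unchanged
        from fissureintegrity.boundary import FissureKind
        from fissureintegrity.metrics import fi_percent
        gt = default_case.gt_integrity[FissureKind.LOBL]
        surf = gt.data > 0
        out = postprocess_prediction(gt.data, surf)
        changed = (out != gt.data).mean()
        assert changed < 0.005
        assert abs(fi_percent(out) - fi_percent(gt)) < 2.0

    def test_all_background_raw_raises(self):
        surf = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(PostprocessError):
            postprocess_prediction(np.zeros((3, 3, 3), dtype=np.uint8), surf)

    def test_support_equals_surface_exactly(self, rng):
        for _ in range(10):
            raw, surf = random_surface_mask(rng)
            out = postprocess_prediction(raw, surf)
            np.testing.assert_array_equal(out > 0, surf)

    def test_matches_independent_reimplementation(self, rng):
        for _ in range(20):
            raw, surf = random_surface_mask(rng)
            out = postprocess_prediction(raw, surf)
            np.testing.assert_array_equal(out, naive_pipeline(raw, surf))

    def test_label_swap_equivariance_on_tie_free_masks(self, rng):
        for _ in range(20):
            raw, surf = random_surface_mask(rng)
            out = postprocess_prediction(raw, surf)
            swapped_raw = raw.copy()
            swapped_raw[raw == 1] = 2
            swapped_raw[raw == 2] = 1
            out_sw = postprocess_prediction(swapped_raw, surf)
            # compare only where no fill/smooth ties occurred: voxels where
            # swapping commutes
            swap_out = out.copy()
            swap_out[out == 1] = 2
            swap_out[out == 2] = 1
            agree = (out_sw == swap_out)
            # ties are rare; demand near-complete equivariance
            assert agree.mean() > 0.95
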