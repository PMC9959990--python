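"""Border repair: boundary tracing, hull, merge, rasterization, closing.

Independent oracles: an erosion-difference boundary oracle, an O(n^2)
gift-wrapping convex hull, a flood-fill interior check and a distance
transform for stroke thickness.
"""

import numpy as np
import pytest
from scipy import ndimage as ndi

from sootylung import border_repair as br
from sootylung.evaluation import convex_deficiency, dice


def random_blob(seed, shape=(48, 48)):
    """Simply connected random blob: union of discs, filled, largest kept."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mask = np.zeros(shape, bool)
    cy, cx = shape[0] / 2, shape[1] / 2
    for _ in range(rng.integers(3, 7)):
        r = rng.uniform(4, 9)
        dy, dx = rng.uniform(-8, 8, 2)
        mask |= (yy - cy - dy) ** 2 + (xx - cx - dx) ** 2 <= r**2
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), int))
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == 1 + int(np.argmax(sizes))


def gift_wrap_hull(points):
    """O(n^2) gift wrapping in (x=col, y=row) coordinates; returns vertex set."""
    pts = [tuple(p) for p in np.unique(np.asarray(points), axis=0)]
    if len(pts) <= 2:
        return set(pts)
    start = min(pts, key=lambda p: (p[1], p[0]))  # leftmost col, then top row
    hull = [start]
    while True:
        candidate = pts[0] if pts[0] != hull[-1] else pts[1]
        for p in pts:
            if p == hull[-1]:
                continue
            # cross product in (col, row) plane
            o, a, b = hull[-1], candidate, p
            cross = (a[1] - o[1]) * (b[0] - o[0]) - (a[0] - o[0]) * (b[1] - o[1])
            if cross > 0 or (cross == 0 and
                             np.hypot(b[0] - o[0], b[1] - o[1]) >
                             np.hypot(a[0] - o[0], a[1] - o[1])):
                candidate = p
        if candidate == start:
            break
        hull.append(candidate)
    return set(hull)


class TestTraceBoundary:
    def test_three_by_three_square_clockwise_from_top_left(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        pts = br.trace_boundary(mask)
        expected = [(1, 1), (1, 2), (1, 3), (2, 3), (3, 3), (3, 2), (3, 1), (2, 1)]
        assert [tuple(p) for p in pts] == expected

    def test_single_pixel(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        assert [tuple(p) for p in br.trace_boundary(mask)] == [(1, 1)]

    @pytest.mark.parametrize("seed", range(15))
    def test_blob_matches_erosion_difference_oracle(self, seed):
        mask = random_blob(seed)
        pts = br.trace_boundary(mask)
        got = {tuple(p) for p in pts}
        cross = ndi.generate_binary_structure(2, 1)
        oracle = mask & ~ndi.binary_erosion(mask, structure=cross)
        assert got == {tuple(p) for p in np.argwhere(oracle)}
        # every point has a background 8-neighbour; consecutive points 8-adjacent
        padded = np.pad(mask, 1)
        for r, c in pts:
            assert not padded[r: r + 3, c: c + 3].all()
        diffs = np.abs(np.diff(pts, axis=0)).max(axis=1)
        assert (diffs <= 1).all()

    def test_multi_component_rejected(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = mask[4, 4] = True
        with pytest.raises(ValueError, match="component"):
            br.trace_boundary(mask)


class TestConvexHull:
    def test_square_corners_with_centre(self):
        pts = np.array([[0, 0], [0, 4], [4, 4], [4, 0], [2, 2]])
        hull = br.convex_hull_indices(pts)
        assert {tuple(p) for p in hull} == {(0, 0), (0, 4), (4, 4), (4, 0)}

    def test_collinear_returns_endpoints(self):
        pts = np.array([[1, 1], [2, 2], [3, 3], [4, 4]])
        hull = br.convex_hull_indices(pts)
        assert {tuple(p) for p in hull} == {(1, 1), (4, 4)}

    @pytest.mark.parametrize("seed", range(30))
    def test_random_points_match_gift_wrap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.integers(0, 40, (30, 2))
        hull = br.convex_hull_indices(pts)
        got = {tuple(p) for p in hull}
        oracle = {(r, c) for c, r in gift_wrap_hull(pts[:, ::-1])}
        assert got == oracle

    def test_clockwise_orientation(self):
        mask = random_blob(3)
        chi = br.trace_boundary(mask)
        hull = br.convex_hull_indices(chi)
        # shoelace in (col, row) screen coords: clockwise -> positive area sum
        r, c = hull[:, 0].astype(float), hull[:, 1].astype(float)
        area2 = np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r)
        assert area2 > 0


class TestMergeIndexSets:
    def test_convex_region_unchanged(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        chi = br.trace_boundary(mask)
        hull = br.convex_hull_indices(chi)
        merged = br.merge_index_sets(chi, hull, 3.0)
        assert np.array_equal(merged, chi)

    def test_deep_notch_replaced_by_chord(self):
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        mask[13:17, 15:25] = False  # deep slot from the right edge
        chi = br.trace_boundary(mask)
        hull = br.convex_hull_indices(chi)
        merged = br.merge_index_sets(chi, hull, 3.0)
        assert len(merged) < len(chi)
        # no merged point deep inside the notch
        inside_notch = [(r, c) for r, c in merged if 13 <= r <= 16 and 16 <= c < 24]
        assert inside_notch == []

    def test_empty_boundary_rejected(self):
        with pytest.raises(ValueError):
            br.merge_index_sets(np.empty((0, 2), int), np.empty((0, 2), int))


class TestRasterizeThickContour:
    def test_square_ring_interior_matches_square(self):
        s = np.array([[10, 10], [10, 40], [40, 40], [40, 10]])
        ring = br.rasterize_thick_contour(s, 4, (51, 51))
        filled = ndi.binary_fill_holes(ring)
        interior = filled & ~ring
        assert interior[25, 25]
        assert not interior[5, 5]
        # interior approximates the square's strict interior
        square = np.zeros((51, 51), bool)
        square[11:40, 11:40] = True
        assert dice(filled, ndi.binary_dilation(square, iterations=2)) > 0.9

    def test_thickness_at_least_n(self):
        s = np.array([[10, 10], [10, 40], [40, 40], [40, 10]])
        n = 4
        ring = br.rasterize_thick_contour(s, n, (51, 51))
        dt = ndi.distance_transform_edt(ring)
        assert 2 * dt.max() + 1 >= n  # stroke supports an inscribed width >= n

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            br.rasterize_thick_contour(np.array([[3, 3], [3, 3]]), 4, (10, 10))
        with pytest.raises(ValueError):
            br.rasterize_thick_contour(np.array([[1, 1], [5, 5]]), 3, (10, 10))

    def test_two_points_give_open_stroke_not_ring(self):
        seg2 = br.rasterize_thick_contour(np.array([[5, 5], [5, 20]]), 4, (26, 26))
        interior = ndi.binary_fill_holes(seg2) & ~seg2
        assert interior.sum() == 0  # nothing enclosed


class TestCloseBorder:
    def test_convex_disc_is_near_fixed_point(self):
        yy, xx = np.mgrid[0:120, 0:120]
        disc = (yy - 60) ** 2 + (xx - 60) ** 2 <= 45**2
        out = br.close_border(disc)
        assert dice(out, disc) >= 0.98

    def test_right_angled_notch_recovered(self):
        yy, xx = np.mgrid[0:120, 0:120]
        disc = (yy - 60) ** 2 + (xx - 60) ** 2 <= 45**2
        slot = (np.abs(yy - 60) <= 6) & (xx >= 72)
        notched, notch = disc & ~slot, disc & slot
        out = br.close_border(notched)
        assert (notched & notch).sum() == 0
        assert (out & notch).sum() / notch.sum() >= 0.95

    def test_line_width_below_four_rejected(self):
        with pytest.raises(ValueError):
            br.NhbccParams(line_width=3).validate()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            br.close_border(np.zeros((10, 10), bool))

    def test_never_shrinks_substance_and_reduces_deficiency(self):
        from sootylung import phantom as ph
        from sootylung import segmentation as seg

        for seed in (1, 2):
            s = ph.generate_phantom(ph.spec_for_class("malignant", "juxtapleural"), seed)
            left, right, _ = seg.segment_lungs(s.image)
            for lobe in (left, right):
                fixed = br.close_border(lobe)
                assert (fixed & lobe).sum() / lobe.sum() >= 0.95
                assert convex_deficiency(fixed) <= convex_deficiency(lobe)

    def test_approximately_idempotent(self, juxtapleural_phantom):
        from sootylung import segmentation as seg

        left, _, _ = seg.segment_lungs(juxtapleural_phantom.image)
        once = br.close_border(left)
        twice = br.close_border(once)
        assert (once ^ twice).sum() <= 0.02 * max(once.sum(), twice.sum())
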