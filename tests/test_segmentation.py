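"""Seeded region growing: Otsu, seed selection, growth, full-lung runs.

Independent oracles: an exhaustive 256-threshold scan for Otsu, a
brute-force ring enumeration for seed selection, and a queue-based BFS
flood fill for region growth.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sootylung import segmentation as seg
from sootylung.evaluation import dice


# ---------------------------------------------------------------------- oracles

def otsu_exhaustive(img):
    """Scan all 256 thresholds, computing between-class variance directly."""
    vals = img.ravel().astype(float)
    best_t, best_v = None, -1.0
    for t in range(256):
        lo, hi = vals[vals <= t], vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return best_t


def flood_fill_oracle(img, seed, threshold, connectivity=8):
    """Queue-based BFS with the strict |I - seed| < threshold rule."""
    h, w = img.shape
    mask = np.zeros((h, w), bool)
    mask[seed.location] = True
    if not abs(int(img[seed.location]) - seed.intensity) < threshold:
        return mask
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    queue = [seed.location]
    while queue:
        r, c = queue.pop()
        for dr, dc in nbrs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] \
                    and abs(int(img[rr, cc]) - seed.intensity) < threshold:
                mask[rr, cc] = True
                queue.append((rr, cc))
    return mask


def ring_scan_oracle(lobe, p):
    """First dark-majority pixel over concentric rings, clockwise from top-left."""
    h, w = lobe.shape
    cr, cc = h // 2, w // 2

    def passes(r, c):
        if not (0 <= r < h and 0 <= c < w) or lobe[r, c] >= p.air_threshold:
            return False
        neigh = [lobe[rr, cc2] for rr in (r - 1, r, r + 1) for cc2 in (c - 1, c, c + 1)
                 if (rr, cc2) != (r, c) and 0 <= rr < h and 0 <= cc2 < w]
        return sum(v < p.air_threshold for v in neigh) > 0.5 * len(neigh)

    if passes(cr, cc):
        return (cr, cc)
    for rad in range(1, max(h, w)):
        ring = [(-rad, c) for c in range(-rad, rad + 1)]
        ring += [(r, rad) for r in range(-rad + 1, rad + 1)]
        ring += [(rad, c) for c in range(rad - 1, -rad - 1, -1)]
        ring += [(r, -rad) for r in range(rad - 1, -rad, -1)]
        for dr, dc in ring:
            if passes(cr + dr, cc + dc):
                return (cr + dr, cc + dc)
    return None


# ------------------------------------------------------------------------ Otsu

class TestOtsu:
    def test_two_level_image_matches_exhaustive_scan(self, rng):
        img = np.where(rng.random((20, 20)) < 0.5, 50, 200).astype(np.uint8)
        t = seg.otsu_threshold(img)
        assert t == otsu_exhaustive(img) == 50  # smallest maximizing threshold

    def test_four_pixel_image(self):
        img = np.array([[10, 10], [200, 200]], dtype=np.uint8)
        t = seg.otsu_threshold(img)
        assert t == otsu_exhaustive(img)
        assert 10 <= t < 200

    @pytest.mark.parametrize("seed", range(10))
    def test_random_images_match_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert seg.otsu_threshold(img) == otsu_exhaustive(img)

    def test_constant_image_rejected(self):
        with pytest.raises(seg.DegenerateImage):
            seg.otsu_threshold(np.full((8, 8), 7, np.uint8))


# ----------------------------------------------------------------- split_lobes

class TestSplitLobes:
    def test_even_and_odd_widths(self, rng):
        img = rng.integers(0, 256, (10, 256)).astype(np.uint8)
        left, right, (_, mid) = seg.split_lobes(img)
        assert left.shape[1] == right.shape[1] == 128
        odd = rng.integers(0, 256, (10, 255)).astype(np.uint8)
        l2, r2, _ = seg.split_lobes(odd)
        assert (l2.shape[1], r2.shape[1]) == (127, 128)  # left gets the smaller

    def test_recompose_identity(self, rng):
        img = rng.integers(0, 256, (9, 31)).astype(np.uint8)
        left, right, (_, mid) = seg.split_lobes(img)
        assert np.array_equal(np.hstack([left, right]), img)
        assert mid == left.shape[1]


# ----------------------------------------------------------------- select_seed

class TestSelectSeed:
    def test_dark_centre_accepted_immediately(self):
        img = np.full((9, 9), 20, np.uint8)
        s = seg.select_seed(img)
        assert s.location == (4, 4) and s.intensity == 20

    def test_offset_dark_block_matches_ring_oracle(self):
        img = np.full((21, 21), 200, np.uint8)
        img[2:7, 2:7] = 5  # dark block up-left of centre
        p = seg.AssrgParams()
        s = seg.select_seed(img, p)
        assert s.location == ring_scan_oracle(img, p)
        assert img[s.location] < p.air_threshold

    @pytest.mark.parametrize("seed", range(10))
    def test_random_images_match_ring_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (15, 17)).astype(np.uint8)
        p = seg.AssrgParams()
        oracle = ring_scan_oracle(img, p)
        if oracle is None:
            with pytest.raises(seg.NoAirRegion):
                seg.select_seed(img, p)
        else:
            assert seg.select_seed(img, p).location == oracle

    def test_all_bright_raises(self):
        with pytest.raises(seg.NoAirRegion):
            seg.select_seed(np.full((9, 9), 200, np.uint8))


# ----------------------------------------------------------------- region_grow

class TestRegionGrow:
    def test_uniform_image_fills_everything(self):
        img = np.full((7, 7), 30, np.uint8)
        mask = seg.region_grow(img, seg.Seed((3, 3), 30),
                               seg.AssrgParams(grow_threshold=1))
        assert mask.all()

    def test_zero_threshold_returns_only_seed(self):
        img = np.full((7, 7), 30, np.uint8)
        mask = seg.region_grow(img, seg.Seed((3, 3), 30),
                               seg.AssrgParams(grow_threshold=0))
        assert mask.sum() == 1 and mask[3, 3]

    def test_two_plateau_image_matches_flood_fill(self):
        img = np.full((7, 7), 100, np.uint8)
        img[:, :3] = 10
        p = seg.AssrgParams(grow_threshold=25)
        s = seg.Seed((3, 1), 10)
        mask = seg.region_grow(img, s, p)
        assert np.array_equal(mask, flood_fill_oracle(img, s, 25))
        assert mask.sum() == 21

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(25))
    def test_random_images_equal_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        loc = tuple(rng.integers(0, 16, 2))
        s = seg.Seed(loc, int(img[loc]))
        p = seg.AssrgParams(grow_threshold=int(rng.integers(0, 60)),
                            connectivity=connectivity)
        got = seg.region_grow(img, s, p)
        assert np.array_equal(got, flood_fill_oracle(img, s, p.grow_threshold,
                                                     connectivity))

    @given(t1=st.integers(0, 40), t2=st.integers(0, 40), seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, t1, t2, seed):
        if t1 > t2:
            t1, t2 = t2, t1
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 120, (12, 12)).astype(np.uint8)
        s = seg.Seed((6, 6), int(img[6, 6]))
        m1 = seg.region_grow(img, s, seg.AssrgParams(grow_threshold=t1))
        m2 = seg.region_grow(img, s, seg.AssrgParams(grow_threshold=t2))
        assert not (m1 & ~m2).any()  # m1 subset of m2

    def test_connected_and_contains_seed(self, rng):
        from scipy import ndimage as ndi

        img = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        s = seg.Seed((10, 10), int(img[10, 10]))
        mask = seg.region_grow(img, s, seg.AssrgParams(grow_threshold=40))
        assert mask[10, 10]
        _, n = ndi.label(mask, structure=np.ones((3, 3), int))
        assert n == 1

    def test_shift_invariance(self, rng):
        img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        big = np.full((20, 20), 255, np.uint8)
        big[4:16, 4:16] = img
        s = seg.Seed((6, 6), int(img[6, 6]))
        s_shift = seg.Seed((10, 10), int(img[6, 6]))
        m = seg.region_grow(img, s, seg.AssrgParams(grow_threshold=30))
        m_big = seg.region_grow(big, s_shift, seg.AssrgParams(grow_threshold=30))
        assert np.array_equal(m_big[4:16, 4:16], m)


# --------------------------------------------------------------- segment_lungs

class TestSegmentLungs:
    def test_phantom_lobes_recovered(self, normal_phantom):
        left, right, seeds = seg.segment_lungs(normal_phantom.image)
        assert dice(left, normal_phantom.left_lobe_mask) >= 0.95
        assert dice(right, normal_phantom.right_lobe_mask) >= 0.95
        assert not (left & right).any()
        assert {"left", "right"} == set(seeds)

    def test_lobeless_bright_image_raises_with_side(self):
        img = np.full((64, 64), 200, np.uint8)
        with pytest.raises(seg.NoAirRegion, match="left"):
            seg.segment_lungs(img)
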