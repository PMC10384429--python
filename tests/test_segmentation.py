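"""Hue-band segmentation and connected-component area filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lycosense import (
    FruitMask,
    ImageHSV,
    SegmentationConfig,
    filter_small_regions,
    mask_jaccard,
    segment_fruit,
)


def _uniform_hsv(h, s=0.8, v=0.8, shape=(10, 12)):
    px = np.empty(shape + (3,))
    px[..., 0], px[..., 1], px[..., 2] = h, s, v
    return ImageHSV(px)


def _flood_fill_areas(mask, connectivity=8):
    """Exhaustive BFS component labeling — the independent oracle."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    areas = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack, area = [(sy, sx)], 0
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                area += 1
                for dy, dx in nbrs:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            areas.append(area)
    return sorted(areas)


class TestSegmentFruit:
    def test_background_hue_inside_band_gives_empty_mask(self):
        m = segment_fruit(_uniform_hsv(0.65))
        assert m.n_pixels == 0 and m.n_components == 0

    @pytest.mark.parametrize("hue", [0.0, 0.33, 0.1, 0.9])
    def test_fruit_hues_outside_band_survive(self, hue):
        # red (~0), green (~0.33), orange and magenta-red must all segment as fruit
        m = segment_fruit(_uniform_hsv(hue))
        assert m.mask.all()

    @pytest.mark.parametrize("hue,expected", [(0.466, False), (0.842, False), (0.465, True), (0.843, True)])
    def test_band_edges_are_background_inclusive(self, hue, expected):
        assert segment_fruit(_uniform_hsv(hue)).mask.all() == expected

    def test_matches_per_pixel_threshold_oracle(self, rng):
        px = rng.random((16, 16, 3))
        cfg = SegmentationConfig(s_range=(0.1, 0.9), v_range=(0.2, 1.0))
        got = segment_fruit(ImageHSV(px), cfg).mask
        for y in range(16):
            for x in range(16):
                h, s, v = px[y, x]
                expect = (
                    not (cfg.h_background_low <= h <= cfg.h_background_high)
                    and cfg.s_range[0] <= s <= cfg.s_range[1]
                    and cfg.v_range[0] <= v <= cfg.v_range[1]
                )
                assert got[y, x] == expect

    def test_translation_equivariance(self, rng):
        px = rng.random((8, 8, 3))
        big = np.zeros((12, 12, 3))
        big[..., 0] = 0.65  # background hue
        big[2:10, 3:11] = px
        inner = segment_fruit(ImageHSV(px)).mask
        outer = segment_fruit(ImageHSV(big)).mask
        np.testing.assert_array_equal(outer[2:10, 3:11], inner)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            SegmentationConfig(h_background_low=0.9, h_background_high=0.5)


class TestFilterSmallRegions:
    def test_printed_400px_rule_keeps_exactly_two_of_399_400_401(self):
        # three 1-px-tall strips of 399, 400 and 401 px, mutually non-adjacent
        mask = np.zeros((5, 410), dtype=bool)
        mask[0, :399] = True
        mask[2, :400] = True
        mask[4, :401] = True
        out = filter_small_regions(FruitMask(mask), min_area=400)
        assert out.n_components == 2
        assert sorted(out.areas) == [400, 401]

    def test_empty_mask_passes_through(self):
        out = filter_small_regions(FruitMask(np.zeros((4, 4), dtype=bool)), 400)
        assert out.n_pixels == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(0, 40))
    def test_idempotent_and_anti_extensive(self, seed, min_area):
        mask = np.random.default_rng(seed).random((24, 24)) < 0.35
        m = FruitMask(mask)
        once = filter_small_regions(m, min_area)
        twice = filter_small_regions(once, min_area)
        np.testing.assert_array_equal(once.mask, twice.mask)
        assert not np.any(once.mask & ~mask)  # output subset of input

    def test_kept_components_unchanged(self, rng):
        mask = rng.random((32, 32)) < 0.3
        out = filter_small_regions(FruitMask(mask), 5)
        assert sorted(out.areas) == [a for a in sorted(FruitMask(mask).areas) if a >= 5]


class TestComponentAreasOracle:
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_areas_match_exhaustive_flood_fill(self, connectivity, rng):
        for _ in range(10):
            mask = rng.random((32, 32)) < 0.4
            m = FruitMask(mask, connectivity=connectivity)
            assert sorted(m.areas) == _flood_fill_areas(mask, connectivity)
            assert m.n_components == len(m.areas)


def test_jaccard_bounds():
    a = np.zeros((4, 4), dtype=bool)
    b = a.copy()
    assert mask_jaccard(a, b) == 1.0
    b[0, 0] = True
    assert mask_jaccard(a, b) == 0.0
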