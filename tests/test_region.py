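"""Tests of shape-factor statistics and contour extraction."""
import numpy as np
import pytest
from scipy import ndimage

from corneaseg.region import (
    Contour,
    EmptyMaskError,
    SelectionError,
    RegionStats,
    connected_regions,
    extract_contour,
    fill_contour,
    perimeter,
    select_corneal_region,
    shape_factor,
)

from conftest import random_blob_mask


def disk_mask(radius: int, pad: int = 4) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n] - (radius + pad)
    return yy**2 + xx**2 <= radius**2


class TestShapeFactor:
    def test_large_disk_is_one(self):
        fs = shape_factor(disk_mask(60))
        assert fs == pytest.approx(1.0, rel=0.10)

    def test_square_matches_closed_form(self):
        # continuous square: Fs = 4/pi; the boundary trace visits 4(a-1)
        # axial steps, each weighted by the corrected chain length 0.980
        a = 100
        mask = np.zeros((a + 4, a + 4), bool)
        mask[2 : 2 + a, 2 : 2 + a] = True
        expected = (0.980 * 4 * (a - 1)) ** 2 / (4 * np.pi * a * a)
        assert shape_factor(mask) == pytest.approx(expected, rel=1e-6)
        assert shape_factor(mask) == pytest.approx(4 / np.pi, rel=0.10)

    def test_elongated_rectangle_grows_with_length(self):
        values = []
        for n in (20, 60, 180):
            mask = np.zeros((8, n + 4), bool)
            mask[3:5, 2 : 2 + n] = True  # 2 x n bar
            values.append(shape_factor(mask))
        assert values[0] < values[1] < values[2]
        assert values[2] > 10  # strongly elongated regions exceed the prior

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        blob = random_blob_mask(rng)
        base = np.zeros((60, 60), bool)
        base[5 : 5 + blob.shape[0], 5 : 5 + blob.shape[1]] = blob
        ref = shape_factor(base)
        for dr, dc in [(0, 20), (20, 0), (15, 15)]:
            shifted = np.roll(np.roll(base, dr, axis=0), dc, axis=1)
            assert shape_factor(shifted) == pytest.approx(ref, abs=1e-12)

    def test_approximate_scale_invariance(self):
        small, large = shape_factor(disk_mask(50)), shape_factor(disk_mask(100))
        assert small == pytest.approx(large, rel=0.10)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            shape_factor(np.zeros((5, 5), bool))

    def test_isoperimetric_lower_bound_on_random_blobs(self):
        # the bound holds above ~50 px where discretization error is small
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 20:
            blob = random_blob_mask(rng)
            if blob.sum() < 60:
                continue
            assert shape_factor(blob) >= 1.0 - 0.1
            checked += 1


class TestContour:
    def test_3x3_block_has_eight_boundary_pixels(self):
        mask = np.zeros((5, 5), bool)
        mask[0:3, 0:3] = True
        pts = extract_contour(mask).points
        assert len(pts) == 8
        assert not any((r, c) == (1, 1) for r, c in pts)

    def test_single_pixel(self):
        mask = np.zeros((4, 4), bool)
        mask[2, 1] = True
        c = extract_contour(mask)
        assert len(c) == 1 and tuple(c.points[0]) == (2, 1)
        assert perimeter(mask) == 4.0

    def test_starts_topmost_then_leftmost(self):
        rng = np.random.default_rng(3)
        blob = random_blob_mask(rng)
        pts = extract_contour(blob).points
        rows, cols = np.nonzero(blob)
        top = rows.min()
        assert pts[0, 0] == top
        assert pts[0, 1] == cols[rows == top].min()

    def test_consecutive_points_8_connected_and_closed(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = extract_contour(random_blob_mask(rng)).points
            if len(pts) < 2:
                continue
            closed = np.vstack([pts, pts[:1]])
            steps = np.abs(np.diff(closed, axis=0))
            assert (steps.max(axis=1) == 1).all()

    def test_contour_set_matches_brute_force_boundary(self):
        # oracle: mask pixels with a background 4-neighbor or on the frame edge
        rng = np.random.default_rng(11)
        for _ in range(25):
            mask = random_blob_mask(rng)
            pts = extract_contour(mask).points
            got = set(map(tuple, pts))
            h, w = mask.shape
            expected = set()
            for r, c in zip(*np.nonzero(mask)):
                if r in (0, h - 1) or c in (0, w - 1):
                    expected.add((r, c))
                    continue
                if not (
                    mask[r - 1, c] and mask[r + 1, c]
                    and mask[r, c - 1] and mask[r, c + 1]
                ):
                    expected.add((r, c))
            assert got == expected

    def test_trace_fill_round_trip(self):
        rng = np.random.default_rng(21)
        for _ in range(15):
            mask = random_blob_mask(rng)
            contour = extract_contour(mask)
            assert np.array_equal(fill_contour(contour, mask.shape), mask)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            extract_contour(np.zeros((5, 5), bool))


class TestConnectedRegions:
    def test_square_on_background(self):
        lm = np.zeros((30, 30), np.int32)
        lm[10:20, 10:20] = 1
        regions = connected_regions(lm, min_area=50)
        assert len(regions) == 2
        labels = sorted(r.label for r in regions)
        assert labels == [0, 1]

    def test_small_components_dropped(self):
        lm = np.zeros((30, 30), np.int32)
        lm[1:4, 1:4] = 1  # 9 px < default-scaled min area of 50
        regions = connected_regions(lm, min_area=50)
        assert [r.label for r in regions] == [0]

    def test_component_count_matches_flood_fill_oracle(self):
        def flood_count(lm):
            seen = np.zeros(lm.shape, bool)
            count = 0
            for r0, c0 in np.ndindex(lm.shape):
                if seen[r0, c0]:
                    continue
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < lm.shape[0]
                                and 0 <= cc < lm.shape[1]
                                and not seen[rr, cc]
                                and lm[rr, cc] == lm[r, c]
                            ):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
            return count

        rng = np.random.default_rng(7)
        for _ in range(10):
            lm = rng.integers(0, 3, (20, 20)).astype(np.int32)
            regions = connected_regions(lm, min_area=1)
            assert len(regions) == flood_count(lm)


class TestSelection:
    def _stats(self, label, fs, area, top=0.0):
        return RegionStats(
            label=label,
            component_id=1,
            area=area,
            perimeter=1.0,
            shape_factor=fs,
            touches_top_fraction=top,
            mask=np.ones((1, 1), bool),
        )

    def test_picks_nearest_to_target(self):
        regions = [
            self._stats(0, 1.2, 100),
            self._stats(1, 9.4, 100),
            self._stats(2, 40.0, 100),
        ]
        assert select_corneal_region(regions, 10.0).shape_factor == 9.4

    def test_single_region_returned_regardless(self):
        only = self._stats(0, 55.0, 10)
        assert select_corneal_region([only], 10.0) is only

    def test_area_breaks_ties(self):
        regions = [self._stats(0, 9.0, 100), self._stats(1, 11.0, 500)]
        assert select_corneal_region(regions, 10.0).area == 500

    def test_top_border_regions_excluded(self):
        sky = self._stats(0, 10.0, 5000, top=0.9)
        band = self._stats(1, 8.0, 1000, top=0.0)
        assert select_corneal_region([sky, band], 10.0) is band

    def test_empty_raises(self):
        with pytest.raises(SelectionError):
            select_corneal_region([], 10.0)


def test_selection_picks_band_on_all_clean_frames(small_clean_video):
    _, video, gt = small_clean_video
    mid = 0.5
    for t in range(video.n_frames):
        lm = (video.frames[t] > mid).astype(np.int32)
        regions = connected_regions(lm)
        chosen = select_corneal_region(regions, 10.0)
        assert chosen.label == 1
        assert np.array_equal(chosen.mask, gt.masks[t])
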