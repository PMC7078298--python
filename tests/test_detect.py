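from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gliaquant import detect
from gliaquant.detect import (
    PUNCTA_PARAMS,
    SPOT_PARAMS,
    CellSet,
    DetectionParams,
    apply_threshold,
    count_cells,
    count_spots,
    dedup_centroids,
    normalize_field,
    segment_centroids,
)
from gliaquant.io import FIELD_AREA_MM2


class TestNormalize:
    def test_scales_to_unit_maximum(self, make_field):
        img = make_field([[0.0, 100.0], [200.0, 50.0]])
        norm = normalize_field(img)
        np.testing.assert_allclose(norm.pixels, [[0.0, 0.5], [1.0, 0.25]])

    def test_all_zero_flags_empty_not_raises(self, make_field):
        norm = normalize_field(make_field(np.zeros((8, 8))))
        assert "empty_field" in norm.flags
        assert norm.pixels.sum() == 0

    def test_brightness_scale_invariance(self, make_field, rng):
        base = rng.uniform(0, 80, size=(20, 20))
        a = normalize_field(make_field(base))
        b = normalize_field(make_field(3.0 * base))
        np.testing.assert_allclose(a.pixels, b.pixels)


class TestThreshold:
    def test_boundary_is_kept_below_is_dropped(self, make_field):
        norm = normalize_field(make_field([[0.19 * 100, 0.20 * 100, 100.0]]))
        mask = apply_threshold(norm, DetectionParams(threshold=0.2))
        assert mask.tolist() == [[False, True, True]]

    def test_all_ones_all_true(self, make_field):
        norm = normalize_field(make_field(np.full((5, 5), 7.0)))
        assert apply_threshold(norm, DetectionParams()).all()

    def test_matches_elementwise_oracle(self, make_field, rng):
        img = make_field(rng.uniform(0, 255, size=(30, 30)))
        norm = normalize_field(img)
        mask = apply_threshold(norm, DetectionParams(threshold=0.2))
        oracle = np.empty((30, 30), dtype=bool)
        for y in range(30):
            for x in range(30):
                oracle[y, x] = norm.pixels[y, x] >= 0.2
        np.testing.assert_array_equal(mask, oracle)

    def test_rejects_unnormalised_input(self, make_field):
        with pytest.raises(ValueError):
            apply_threshold(make_field(np.full((3, 3), 2.0)), DetectionParams())


def bfs_components(mask):
    """Independent flood-fill segmentation (8-connected)."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        comp = []
        queue = deque([(sy, sx)])
        seen[sy, sx] = True
        while queue:
            y, x = queue.popleft()
            comp.append((y, x))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (
                        0 <= ny < mask.shape[0]
                        and 0 <= nx < mask.shape[1]
                        and mask[ny, nx]
                        and not seen[ny, nx]
                    ):
                        seen[ny, nx] = True
                        queue.append((ny, nx))
        comps.append(comp)
    return comps


class TestSegmentCentroids:
    def test_square_centroid_by_symmetry(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:10, 0:10] = True
        cents = segment_centroids(mask, pixel_size_um=2.0, params=DetectionParams())
        np.testing.assert_allclose(cents, [[9.0, 9.0]])  # (4.5 px, 4.5 px) * 2 um

    def test_two_disjoint_blobs(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:8, 2:8] = True
        mask[20:26, 20:26] = True
        cents = segment_centroids(mask, 1.0, DetectionParams())
        assert len(cents) == 2

    def test_min_segment_filter(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0] = True  # single-pixel noise
        mask[5:8, 5:8] = True
        assert len(segment_centroids(mask, 1.0, DetectionParams(min_segment_px=5))) == 1
        assert len(segment_centroids(mask, 1.0, DetectionParams(min_segment_px=1))) == 2

    def test_matches_flood_fill_mean_oracle(self, rng):
        mask = rng.uniform(size=(40, 40)) < 0.25
        cents = segment_centroids(mask, 1.5, DetectionParams(min_segment_px=1))
        oracle = sorted(
            tuple(1.5 * np.mean(np.array(c), axis=0)) for c in bfs_components(mask)
        )
        got = sorted(map(tuple, cents))
        np.testing.assert_allclose(got, oracle)


def bruteforce_single_linkage(points, min_distance):
    """O(n^2) union-find single-linkage oracle (strict <)."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) < min_distance:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return clusters


class TestDedupCentroids:
    def test_exactly_min_distance_stays_separate(self):
        pts = np.array([[0.0, 0.0], [0.0, 25.0]])
        assert dedup_centroids(pts, DetectionParams(min_distance_um=25.0)).n_cells == 2

    def test_chain_merging_collinear(self):
        # three collinear points at 0.6 * min_distance spacing: one cell
        pts = np.array([[0.0, 0.0], [0.0, 15.0], [0.0, 30.0]])
        cells = dedup_centroids(pts, DetectionParams(min_distance_um=25.0))
        assert cells.n_cells == 1
        np.testing.assert_allclose(cells.centroids_um, [[0.0, 15.0]])

    def test_empty_input(self):
        cells = dedup_centroids(np.empty((0, 2)), DetectionParams())
        assert cells.n_cells == 0

    def test_matches_bruteforce_on_random_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(0, 120))
            pts = rng.uniform(0, 300, size=(n, 2))
            min_d = float(rng.uniform(1, 50))
            got = dedup_centroids(pts, DetectionParams(min_distance_um=min_d))
            ref = bruteforce_single_linkage(pts, min_d)
            assert got.n_cells == len(ref)
            ref_centroids = sorted(
                tuple(pts[m].mean(axis=0)) for m in ref.values()
            )
            np.testing.assert_allclose(
                sorted(map(tuple, got.centroids_um)), ref_centroids
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pts=arrays(
            np.float64,
            st.tuples(st.integers(0, 40), st.just(2)),
            elements=st.floats(0, 200, allow_nan=False),
        ),
        min_d=st.floats(0.5, 60),
    )
    def test_cluster_count_bounds_and_permutation_invariance(self, pts, min_d):
        params = DetectionParams(min_distance_um=min_d)
        got = dedup_centroids(pts, params)
        if len(pts) == 0:
            assert got.n_cells == 0
            return
        assert 1 <= got.n_cells <= len(pts)
        perm = pts[np.random.default_rng(0).permutation(len(pts))]
        again = dedup_centroids(perm, params)
        assert again.n_cells == got.n_cells
        np.testing.assert_allclose(
            np.sort(again.centroids_um, axis=0), np.sort(got.centroids_um, axis=0)
        )

    def test_density_normalisation(self):
        cells = CellSet(
            centroids_um=np.zeros((10, 2)), field_area_mm2=FIELD_AREA_MM2 / 2
        )
        assert cells.density_per_field == pytest.approx(20.0)


class TestCountCells:
    def test_planted_discs_counted_exactly(self, disc_field):
        centers = [(y, x) for y in (30, 90, 150) for x in (30, 90, 150)]
        cells = count_cells(disc_field(centers))
        assert cells.n_cells == 9

    def test_blank_field_counts_zero(self, make_field):
        cells = count_cells(make_field(np.zeros((50, 50))))
        assert cells.n_cells == 0
        assert "empty_field" in cells.flags

    def test_brightness_invariance_end_to_end(self, disc_field):
        img = disc_field([(40, 40), (120, 120)], amplitude=80.0)
        brighter = type(img)(
            pixels=img.pixels * 2.5, pixel_size_um=img.pixel_size_um
        )
        assert count_cells(img).n_cells == count_cells(brighter).n_cells == 2

    def test_adding_distant_cell_adds_one(self, disc_field):
        base = [(40, 40), (40, 120)]
        assert count_cells(disc_field(base)).n_cells == 2
        assert count_cells(disc_field(base + [(150, 150)])).n_cells == 3

    def test_close_spots_merge(self, disc_field):
        # two discs 8 um apart: one segment after merge (< min_distance)
        img = disc_field([(100, 96), (100, 104)], radius_um=3.0)
        assert count_spots(img).n_cells == 1

    def test_spots_counted_with_spot_params(self, disc_field):
        centers = [(30 + 40 * i, 30 + 40 * j) for i in range(4) for j in range(3)]
        img = disc_field(centers, radius_um=2.0)
        assert count_spots(img).n_cells == 12

    def test_param_validation(self):
        with pytest.raises(ValueError):
            DetectionParams(threshold=0.0)
        with pytest.raises(ValueError):
            DetectionParams(min_distance_um=-1)
        with pytest.raises(ValueError):
            DetectionParams(min_segment_px=0)
        assert SPOT_PARAMS.min_segment_px < DetectionParams().min_segment_px
        assert PUNCTA_PARAMS.min_distance_um < SPOT_PARAMS.min_distance_um
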