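import numpy as np
import pytest

from gliaquant import synth
from gliaquant.detect import DetectionParams
from gliaquant.io import max_project
from gliaquant.morph import (
    arbor_area,
    area_fraction,
    automated_morphometry,
    count_vertical_processes,
    extract_tips,
    soma_area,
)


class TestAreaFraction:
    def test_exact_ten_percent(self, make_field):
        img = np.zeros((10, 10))
        img.flat[:10] = 255.0
        res = area_fraction(make_field(img))
        assert res.fraction == pytest.approx(0.10)
        assert res.area_um2 == pytest.approx(10.0)  # 1 um pixels

    def test_all_bright_is_one(self, make_field):
        assert area_fraction(make_field(np.full((8, 8), 200.0))).fraction == 1.0

    def test_empty_field_is_zero(self, make_field):
        res = area_fraction(make_field(np.zeros((8, 8))))
        assert res.fraction == 0.0
        assert "empty_field" in res.flags

    def test_matches_mask_sum_oracle(self, make_field, rng):
        pixels = rng.uniform(0, 255, size=(25, 25))
        res = area_fraction(make_field(pixels), DetectionParams(threshold=0.3))
        norm = pixels / pixels.max()
        oracle = sum(
            norm[y, x] >= 0.3 for y in range(25) for x in range(25)
        ) / 625
        assert res.fraction == pytest.approx(oracle)

    def test_brightness_invariant_and_threshold_monotone(self, make_field, rng):
        pixels = rng.uniform(0, 100, size=(30, 30))
        f1 = area_fraction(make_field(pixels)).fraction
        f2 = area_fraction(make_field(pixels * 2.0)).fraction
        assert f1 == pytest.approx(f2)
        fracs = [
            area_fraction(make_field(pixels), DetectionParams(threshold=t)).fraction
            for t in (0.1, 0.3, 0.5, 0.7)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_otsu_option_runs(self, disc_field):
        img = disc_field([(50, 50)], radius_um=10)
        assert 0 < area_fraction(img, method="otsu").fraction < 1


class TestSomaArea:
    def test_square_contour(self):
        sq = np.array([[0, 0], [0, 10], [10, 10], [10, 0]], dtype=float)
        assert soma_area(contour_um=sq) == pytest.approx(100.0)

    def test_triangle_shoelace(self):
        tri = np.array([[0, 0], [0, 4], [3, 0]], dtype=float)
        assert soma_area(contour_um=tri) == pytest.approx(6.0)

    def test_closed_polygon_with_repeated_vertex(self):
        sq = np.array([[0, 0], [0, 2], [2, 2], [2, 0], [0, 0]], dtype=float)
        assert soma_area(contour_um=sq) == pytest.approx(4.0)

    def test_self_intersecting_rejected(self):
        bow = np.array([[0, 0], [2, 2], [0, 2], [2, 0]], dtype=float)
        with pytest.raises(ValueError, match="self-intersecting"):
            soma_area(contour_um=bow)

    def test_mask_pathway(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:6, 2:7] = True  # 20 px
        assert soma_area(mask=mask, pixel_size_um=0.5) == pytest.approx(20 * 0.25)
        with pytest.raises(ValueError):
            soma_area(mask=np.zeros((4, 4), dtype=bool), pixel_size_um=1.0)

    def test_exactly_one_input_required(self):
        with pytest.raises(ValueError):
            soma_area()

    def test_synthetic_disc_near_pi_r_squared(self):
        spec = synth.FieldSpec(
            n_cells=1,
            n_processes_per_cell=(0, 0),
            soma_radius_um=(6.0, 0.0),
            min_spacing_um=0.0,
            background_level=0.0,
            seed=3,
            field_side_px=256,
            n_planes=1,
        )
        stack, truth = synth.render_field(spec)
        r = truth.cells[0].soma_radius_um
        # rasterised area within a perimeter-pixel band of the analytic disc
        px = spec.pixel_size_um
        assert truth.cells[0].soma_area_um2 == pytest.approx(
            np.pi * r**2, abs=2 * np.pi * r * 1.5 * px
        )


class TestArborArea:
    def test_square_tips(self):
        tips = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        res = arbor_area(tips)
        assert res.area_um2 == pytest.approx(100.0)
        assert not res.degenerate

    def test_collinear_tips_degenerate(self):
        res = arbor_area(np.array([[0, 0], [1, 1], [2, 2]], dtype=float))
        assert res.area_um2 == 0.0
        assert res.degenerate

    def test_too_few_tips_degenerate(self):
        assert arbor_area(np.array([[0, 0], [5, 5]], dtype=float)).degenerate

    def test_matches_independent_hull_oracle(self, rng):
        import shapely.geometry as sg

        for _ in range(30):
            pts = rng.uniform(0, 50, size=(int(rng.integers(3, 21)), 2))
            got = arbor_area(pts).area_um2
            ref = sg.MultiPoint([tuple(p) for p in pts]).convex_hull.area
            assert got == pytest.approx(ref, abs=1e-9)

    def test_hull_dominates_subsets_and_permutation_invariant(self, rng):
        pts = rng.uniform(0, 50, size=(12, 2))
        full = arbor_area(pts).area_um2
        sub = arbor_area(pts[:7]).area_um2
        assert full >= sub - 1e-12
        shuffled = pts[rng.permutation(12)]
        assert arbor_area(shuffled).area_um2 == pytest.approx(full)


class TestExtractTips:
    def test_straight_line_two_tips(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 2:18] = True
        tips = extract_tips(mask, pixel_size_um=1.0)
        assert len(tips) == 2

    def test_plus_shape_four_tips(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[10, 2:19] = True
        mask[2:19, 10] = True
        assert len(extract_tips(mask, 1.0)) == 4

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_tips(np.zeros((5, 5), dtype=bool), 1.0)

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_star_cell_recovers_process_count(self, k):
        spec = synth.FieldSpec(
            n_cells=1,
            n_processes_per_cell=(k, k),
            arbor_radius_um=(15.0, 0.5),
            min_spacing_um=40.0,
            background_level=0.0,
            antialias=False,
            seed=11 + k,
            field_side_px=256,
            n_planes=1,
        )
        stack, truth = synth.render_field(spec)
        img = max_project(stack)
        tips = extract_tips(img.pixels > 0, img.pixel_size_um)
        assert len(tips) == k


class TestVerticalProcesses:
    def test_blank_plane_zero(self, make_field):
        assert count_vertical_processes(make_field(np.zeros((64, 64)))) == 0

    def test_planted_puncta_recovered(self):
        spec = synth.FieldSpec(
            n_puncta=15, min_spacing_um=14.0, seed=5, field_side_px=256
        )
        plane, truth = synth.render_puncta_plane(spec)
        assert count_vertical_processes(plane) == truth.n_puncta == 15

    def test_close_puncta_merge_to_one(self, disc_field):
        # two puncta 3 um apart, inside the 5 um punctum merge radius
        img = disc_field([(100.0, 99.0), (100.0, 102.0)], radius_um=1.2)
        assert count_vertical_processes(img) == 1


class TestAutomatedMorphometry:
    def test_recovers_soma_and_arbor_scale(self):
        spec = synth.FieldSpec(
            n_cells=8,
            soma_radius_um=(5.0, 0.1),
            arbor_radius_um=(14.0, 0.5),
            min_spacing_um=36.0,
            seed=21,
            field_side_px=512,
            n_planes=1,
        )
        stack, truth = synth.render_field(spec)
        somas, arbors = automated_morphometry(max_project(stack))
        assert len(somas) == 8
        # soma core should be on the order of the planted disc area
        assert np.mean(somas) == pytest.approx(np.pi * 25.0, rel=0.5)
        planted_hulls = [c.arbor_area_um2 for c in truth.cells]
        assert np.mean(arbors) == pytest.approx(np.mean(planted_hulls), rel=0.35)
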