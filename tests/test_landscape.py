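"""Buffer clipping and the class-level landscape metrics."""

import numpy as np
import pytest

from seedscape.landscape import (
    aggregation_index,
    clip_buffer,
    edge_contrast,
    label_patches,
    metric_table,
    patch_density,
    patch_isolation,
    percent_cover,
)
from seedscape.types import (
    BufferError,
    DEFAULT_QUALITY_RANKING,
    DEFAULT_RADII,
    LandCoverRaster,
)

from conftest import full_view
from oracles import landscape_oracle


class TestClipBuffer:
    def test_cell_count_tracks_circle_area(self):
        raster = LandCoverRaster(np.ones((100, 100), dtype=int), 10.0)
        view = clip_buffer(raster, (500.0, 500.0), 300.0)
        assert view.n_cells == pytest.approx(np.pi * 30**2, rel=0.01)

    def test_tiny_radius_single_cell(self):
        raster = LandCoverRaster(np.ones((10, 10), dtype=int), 10.0)
        view = clip_buffer(raster, (55.0, 55.0), 4.0)
        assert view.n_cells == 1

    def test_nested_radii_nested_membership(self):
        raster = LandCoverRaster(np.ones((200, 200), dtype=int), 10.0)
        counts = [
            clip_buffer(raster, (1000.0, 1000.0), r).n_cells
            for r in (100, 200, 300, 400)
        ]
        assert counts == sorted(counts) and len(set(counts)) == 4

    def test_overflowing_buffer_rejected(self):
        raster = LandCoverRaster(np.ones((50, 50), dtype=int), 10.0)
        with pytest.raises(BufferError):
            clip_buffer(raster, (100.0, 100.0), 200.0)


class TestSimpleMetrics:
    def test_percent_cover_counts_cells(self):
        g = np.full((3, 4), 5)
        g[0, :3] = 1
        assert percent_cover(full_view(g), 1) == pytest.approx(25.0)
        assert percent_cover(full_view(g), 2) == 0.0
        assert percent_cover(full_view(np.ones((4, 4), dtype=int)), 1) == 100.0

    def test_cover_sums_to_100(self, rng):
        g = rng.integers(1, 8, size=(12, 12))
        total = sum(percent_cover(full_view(g), c) for c in range(1, 8))
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_diagonal_cells_one_component(self):
        g = np.full((3, 3), 5)
        g[0, 0] = g[1, 1] = 1
        assert label_patches(full_view(g), 1)[1] == 1

    def test_patch_density_increases_on_split(self):
        solid = np.full((4, 8), 5)
        solid[1, 1:5] = 1
        split = np.full((4, 8), 5)
        split[1, 1:3] = 1
        split[1, 5:7] = 1  # same area, two pieces
        v1, v2 = full_view(solid), full_view(split)
        assert patch_density(v2, 1) > patch_density(v1, 1)
        assert patch_density(full_view(np.full((3, 3), 5)), 1) == 0.0


class TestAggregationIndex:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ("block", 100.0),  # 2x2 solid: g = 4 = g_max
            ("isolated", 0.0),  # 4 isolated cells: no shared edge
            ("strip", 75.0),  # 1x4 strip: g = 3, g_max = 4
        ],
    )
    def test_analytic_cases(self, cells, expected):
        g = np.full((5, 6), 5)
        if cells == "block":
            g[1:3, 1:3] = 1
        elif cells == "isolated":
            g[0, 0] = g[0, 2] = g[2, 0] = g[2, 2] = 1
        else:
            g[2, 1:5] = 1
        assert aggregation_index(full_view(g), 1) == pytest.approx(expected)

    def test_absent_class_missing_and_single_cell_zero(self):
        g = np.full((3, 3), 5)
        assert np.isnan(aggregation_index(full_view(g), 1))
        g[1, 1] = 1
        assert aggregation_index(full_view(g), 1) == 0.0


class TestPatchIsolation:
    def test_two_cells_five_apart(self):
        g = np.full((3, 8), 5)
        g[1, 1] = g[1, 6] = 1
        assert patch_isolation(full_view(g), 1) == pytest.approx(50.0)

    def test_single_patch_missing(self):
        g = np.full((3, 3), 5)
        g[1, 1] = 1
        assert np.isnan(patch_isolation(full_view(g), 1))

    def test_translation_invariance(self):
        base = np.full((10, 10), 5)
        base[1, 1] = base[1, 4] = base[5, 2] = 1
        shifted = np.full((10, 10), 5)
        shifted[4, 4] = shifted[4, 7] = shifted[8, 5] = 1
        assert patch_isolation(full_view(base), 1) == pytest.approx(
            patch_isolation(full_view(shifted), 1)
        )


class TestEdgeContrast:
    def test_water_surround_maximal(self):
        g = np.full((4, 4), 7)
        g[1:3, 1:3] = 1
        assert edge_contrast(full_view(g), 1) == pytest.approx(100.0)

    def test_interior_zero(self):
        assert edge_contrast(full_view(np.ones((4, 4), dtype=int)), 1) == 0.0

    def test_mixed_boundary_weighted(self):
        # boundary half cattle pasture (gap 4/6), half secondary forest (1/6)
        g = np.full((3, 3), 5)
        g[1, 1] = 1
        g[0, 1] = g[1, 0] = 2
        assert edge_contrast(full_view(g), 1) == pytest.approx(
            100 * (0.5 * 4 / 6 + 0.5 * 1 / 6), rel=1e-12
        )

    def test_decreases_when_neighbour_rank_improves(self):
        worse = np.full((3, 3), 3)  # floodplain, rank 5
        worse[1, 1] = 1
        better = np.full((3, 3), 2)  # secondary forest, rank 6
        better[1, 1] = 1
        assert edge_contrast(full_view(better), 1) < edge_contrast(full_view(worse), 1)

    def test_invariant_to_relabelling_equal_rank(self):
        # two different non-focal classes given the same rank must be
        # interchangeable on the boundary
        ranking = dict(DEFAULT_QUALITY_RANKING)
        ranking[6] = ranking[5]
        a = np.full((3, 3), 5)
        a[1, 1] = 1
        b = np.full((3, 3), 6)
        b[1, 1] = 1
        assert edge_contrast(full_view(a), 1, ranking) == pytest.approx(
            edge_contrast(full_view(b), 1, ranking)
        )


class TestBruteForceAgreement:
    def test_random_small_grids_match_enumeration(self, rng):
        for _ in range(60):
            nrows = int(rng.integers(3, 9))
            ncols = int(rng.integers(3, 9))
            codes = rng.choice([1, 2, 5, 7], size=(nrows, ncols))
            view = full_view(codes)
            oracle = landscape_oracle(
                view.classes, view.mask, view.cell_size, 1, DEFAULT_QUALITY_RANKING
            )
            got = {
                "PD": patch_density(view, 1),
                "AI": aggregation_index(view, 1),
                "PI": patch_isolation(view, 1),
                "EC": edge_contrast(view, 1),
            }
            for name in ("PD", "AI", "PI", "EC"):
                if np.isnan(oracle[name]):
                    assert np.isnan(got[name]), name
                else:
                    assert got[name] == pytest.approx(oracle[name], abs=1e-9), name

    def test_circular_view_matches_enumeration(self, rng):
        # same oracle but on a genuine circular buffer mask
        grid = rng.choice([1, 2, 5, 7], size=(20, 20))
        raster = LandCoverRaster(grid, 10.0)
        view = clip_buffer(raster, (100.0, 100.0), 70.0)
        oracle = landscape_oracle(
            view.classes, view.mask, view.cell_size, 1, DEFAULT_QUALITY_RANKING
        )
        assert patch_density(view, 1) == pytest.approx(oracle["PD"], abs=1e-9)
        assert aggregation_index(view, 1) == pytest.approx(oracle["AI"], abs=1e-9)
        if np.isnan(oracle["PI"]):
            assert np.isnan(patch_isolation(view, 1))
        else:
            assert patch_isolation(view, 1) == pytest.approx(oracle["PI"], abs=1e-9)
        assert edge_contrast(view, 1) == pytest.approx(oracle["EC"], abs=1e-9)


class TestMetricTable:
    def test_degenerate_all_forest_landscape(self):
        raster = LandCoverRaster(np.ones((400, 400), dtype=int), 10.0)
        centres = {"p0": (2000.0, 2000.0)}
        records = metric_table(raster, centres, radii=(300.0, 500.0))
        by = {(r.metric, r.radius_m): r.value for r in records}
        for radius in (300.0, 500.0):
            assert by[("FC", radius)] == 100.0
            assert by[("SF", radius)] == 0.0
            assert by[("EC", radius)] == 0.0
            assert np.isnan(by[("PI", radius)])
            assert by[("AI", radius)] > 95.0
        assert len(records) == 12

    def test_cardinality_16_patches(self, rng):
        grid = rng.choice([1, 2, 5], size=(120, 120))
        raster = LandCoverRaster(grid, 50.0)
        centres = {
            f"p{i}": (
                float(rng.uniform(2000, 4000)),
                float(rng.uniform(2000, 4000)),
            )
            for i in range(16)
        }
        records = metric_table(raster, centres)
        assert len(records) == 16 * len(DEFAULT_RADII) * 6
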