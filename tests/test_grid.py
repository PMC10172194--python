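"""Spot grid geometry, labelling, registration, and profile extraction."""

import numpy as np
import pandas as pd
import pytest

from conftest import toy_cube
from spatomix.grid import (
    AffineTransform,
    extract_region_profiles,
    extract_spot_profiles,
    fit_landmark_transform,
    label_spots,
    make_spot_grid,
    map_pixels_to_spots,
)


class TestMakeSpotGrid:
    def test_visium_extent_gives_4225_spots(self):
        grid = make_spot_grid((6500, 6500), 100, 55, seed=0)
        assert grid.n_spots == 65 * 65 == 4225

    def test_default_platform_geometry(self):
        grid = make_spot_grid()
        assert grid.diameter == 55.0
        assert grid.spacing == 100.0
        assert all(len(bc) == 16 for bc in grid.spots["barcode"])
        assert grid.spots["barcode"].is_unique

    def test_horizontally_adjacent_spots_are_one_spacing_apart(self):
        grid = make_spot_grid((1000, 1000), 100, 55, seed=0)
        first_row = grid.spots[grid.spots["row_idx"] == 0].sort_values("col_idx")
        dx = np.diff(first_row["center_x"].to_numpy())
        assert np.allclose(dx, 100.0)

    def test_extent_smaller_than_spacing_raises(self):
        with pytest.raises(ValueError, match="invalid-geometry"):
            make_spot_grid((50, 50), 100, 55, seed=0)

    def test_diameter_not_smaller_than_spacing_raises(self):
        with pytest.raises(ValueError, match="invalid-geometry"):
            make_spot_grid((1000, 1000), 100, 100, seed=0)


class TestLabelSpots:
    def test_corner_and_neighbour_labels(self):
        grid = make_spot_grid((500, 500), 100, 55, seed=0)
        relabelled = label_spots(grid)
        spots = relabelled.spots
        top_left = spots.iloc[0]
        assert top_left["label"] == "x1y1"
        right = spots[
            np.isclose(spots["center_x"], top_left["center_x"] + 100)
            & np.isclose(spots["center_y"], top_left["center_y"])
        ]
        below = spots[
            np.isclose(spots["center_x"], top_left["center_x"])
            & np.isclose(spots["center_y"], top_left["center_y"] + 100)
        ]
        assert right["label"].item() == "x2y1"
        assert below["label"].item() == "x1y2"

    def test_duplicate_centers_raise(self):
        grid = make_spot_grid((500, 500), 100, 55, seed=0)
        grid.spots.loc[1, ["center_x", "center_y"]] = grid.spots.loc[
            0, ["center_x", "center_y"]
        ].to_numpy()
        with pytest.raises(ValueError, match="invalid-grid"):
            label_spots(grid)


class TestLandmarkTransform:
    def test_identity_map(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [70.0, 30.0]])
        t = fit_landmark_transform(pts, pts)
        assert np.allclose(t.linear, np.eye(2), atol=1e-9)
        assert np.allclose(t.translation, 0, atol=1e-9)
        assert t.residual_rms < 1e-9

    def test_pure_shift(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        t = fit_landmark_transform(pts, pts + [50.0, -20.0])
        assert np.allclose(t.linear, np.eye(2), atol=1e-9)
        assert np.allclose(t.translation, [50.0, -20.0], atol=1e-9)

    def test_rotation_90_degrees(self):
        pts = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 3.0], [5.0, -1.0]])
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        t = fit_landmark_transform(pts, pts @ rot.T)
        assert np.allclose(t.linear, rot, atol=1e-9)

    def test_collinear_points_raise(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="underdetermined"):
            fit_landmark_transform(pts, pts)

    def test_too_few_pairs_raise(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="underdetermined"):
            fit_landmark_transform(pts, pts)

    def test_round_trip_within_1e6_um(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 6500, size=(8, 2))
        lin = np.array([[1.02, 0.05], [-0.04, 0.98]])
        dst = src @ lin.T + [12.0, -7.0]
        t = fit_landmark_transform(src, dst)
        back = t.inverse().apply(t.apply(src))
        assert np.abs(back - src).max() < 1e-6


class TestPixelAssignment:
    def test_pixel_at_spot_center_maps_to_it(self):
        grid = make_spot_grid((400, 400), 100, 55, seed=0)
        cube = toy_cube(np.ones((1, 2)))
        cube.coords.loc[0, ["x", "y"]] = grid.spots.loc[5, ["center_x", "center_y"]].to_numpy()
        assignment = map_pixels_to_spots(cube, grid, footprint_rule="voronoi")
        assert assignment.spot_labels[assignment.spot_index[0]] == grid.spots.loc[5, "label"]

    def test_aligned_voronoi_gives_4_pixels_per_spot(self):
        # 50 um pitch pixels under a 100 um lattice: 2x2 pixels per cell
        grid = make_spot_grid((400, 400), 100, 55, seed=0)
        n = 8  # 400/50
        cube = toy_cube(np.ones((n * n, 1)), pitch=50.0)
        assignment = map_pixels_to_spots(cube, grid, footprint_rule="voronoi")
        counts = np.bincount(assignment.spot_index, minlength=grid.n_spots)
        assert np.all(counts == 4)

    def test_circle_rule_leaves_distant_pixels_unassigned(self):
        grid = make_spot_grid((400, 400), 100, 55, seed=0)
        cube = toy_cube(np.ones((1, 1)))
        cube.coords.loc[0, ["x", "y"]] = [25.0, 25.0]  # 35.4 um from (50, 50)
        assignment = map_pixels_to_spots(cube, grid, footprint_rule="circle")
        assert assignment.spot_index[0] == -1

    def test_voronoi_assignment_partitions_in_extent_pixels(self):
        grid = make_spot_grid((400, 400), 100, 55, seed=0)
        cube = toy_cube(np.ones((64, 1)), pitch=50.0)
        assignment = map_pixels_to_spots(cube, grid, footprint_rule="voronoi")
        assert assignment.n_assigned == 64  # disjoint by construction: one index per pixel


class TestProfileExtraction:
    def test_mean_of_assigned_pixels(self):
        grid = make_spot_grid((100, 100), 100, 55, seed=0)  # single spot
        cube = toy_cube(np.array([[1.0], [2.0], [3.0], [4.0]]), pitch=50.0)
        assignment = map_pixels_to_spots(cube, grid, footprint_rule="voronoi")
        table = extract_spot_profiles(cube, assignment)
        assert table.values.iloc[0, 0] == pytest.approx(2.5)

    def test_uniform_cube_gives_uniform_profiles(self):
        grid = make_spot_grid((400, 400), 100, 55, seed=0)
        cube = toy_cube(np.full((64, 2), 7.0), pitch=50.0)
        table = extract_spot_profiles(cube, map_pixels_to_spots(cube, grid))
        assert np.allclose(table.values.to_numpy(), 7.0)

    def test_grand_mean_identity_on_balanced_assignment(self):
        grid = make_spot_grid((400, 400), 100, 55, seed=0)
        rng = np.random.default_rng(1)
        cube = toy_cube(rng.uniform(0, 10, size=(64, 3)), pitch=50.0)
        table = extract_spot_profiles(cube, map_pixels_to_spots(cube, grid))
        assert np.allclose(
            table.values.to_numpy().mean(axis=0), cube.intensities.mean(axis=0)
        )

    def test_aggregation_linearity(self):
        grid = make_spot_grid((400, 400), 100, 55, seed=0)
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, size=(64, 2))
        y = rng.uniform(0, 5, size=(64, 2))
        cx, cy, cz = toy_cube(x, pitch=50.0), toy_cube(y, pitch=50.0), toy_cube(
            2 * x + 3 * y, pitch=50.0
        )
        a = map_pixels_to_spots(cx, grid)
        px = extract_spot_profiles(cx, a).values.to_numpy()
        py = extract_spot_profiles(cy, a).values.to_numpy()
        pz = extract_spot_profiles(cz, a).values.to_numpy()
        assert np.allclose(pz, 2 * px + 3 * py)

    def test_spot_without_pixels_flagged_missing_not_zero(self):
        grid = make_spot_grid((200, 200), 100, 55, seed=0)  # 4 spots
        cube = toy_cube(np.ones((1, 1)))
        cube.coords.loc[0, ["x", "y"]] = [50.0, 50.0]
        assignment = map_pixels_to_spots(cube, grid, footprint_rule="circle")
        table = extract_spot_profiles(cube, assignment)
        assert table.missing.sum() == 3
        assert table.values[table.missing].isna().all().all()


class TestRegionProfiles:
    def test_single_region_equals_column_means(self):
        frame = pd.DataFrame(np.arange(12.0).reshape(4, 3), index=list("abcd"))
        means, counts = extract_region_profiles(frame, ["r"] * 4)
        assert np.allclose(means.loc["r"], frame.mean())
        assert counts["r"] == 4

    def test_identical_member_groups_give_identical_rows(self):
        frame = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 6.0], [5.0, 6.0]])
        means, _ = extract_region_profiles(frame, ["p", "q", "p", "q"])
        assert np.allclose(means.loc["p"], means.loc["q"])

    def test_planted_contrast_survives_aggregation(self, small_cube):
        truth = small_cube.meta["true_region"]
        frame = pd.DataFrame(small_cube.intensities, columns=small_cube.feature_ids())
        means, _ = extract_region_profiles(frame, truth)
        ratio = (means.loc["A", "glutamine"] - 2.0) / (means.loc["C", "glutamine"] - 2.0)
        assert 3.5 <= ratio <= 4.5
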