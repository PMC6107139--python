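"""Boundary extraction, node tracking and kymograph tests on analytic shapes."""

import numpy as np
import pytest

from amoeboid.contour import (
    Contour,
    ContourError,
    build_kymograph,
    centroid_distance,
    extract_contour,
    local_curvature,
    local_displacement,
    map_nodes,
    sample_boundary_concentration,
)
from amoeboid.grid import GridSpec, integrate_field
from amoeboid.synthetic import (
    disk_field,
    ellipse_field,
    expanding_disk_series,
    shape_series,
    translating_disk_series,
)

GRID = GridSpec(nx=200, ny=200, dx=0.15, dt=0.002)


def circle_contour(radius=6.0, n=400, center=(0.0, 0.0), phase=0.0):
    t = phase + np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]))


class TestExtractContour:
    def test_disk_level_set_radius(self):
        phi = disk_field(GRID, radius=6.0)
        cont = extract_contour(phi, GRID)
        centre = np.array(GRID.box_size) / 2
        radii = np.hypot(*(cont.nodes - centre).T)
        assert np.all(np.abs(radii - 6.0) < GRID.dx)
        assert cont.n_nodes == 400

    def test_uniform_arc_spacing_and_orientation(self):
        phi = disk_field(GRID, radius=5.0)
        cont = extract_contour(phi, GRID)
        seg = np.roll(cont.nodes, -1, axis=0) - cont.nodes
        lengths = np.hypot(seg[:, 0], seg[:, 1])
        assert lengths.std() / lengths.mean() < 0.01
        assert cont.enclosed_area() > 0  # counterclockwise

    def test_polygon_area_agrees_with_field_integral(self):
        phi = disk_field(GRID, radius=6.0)
        cont = extract_contour(phi, GRID)
        assert cont.enclosed_area() == pytest.approx(integrate_field(phi, GRID), rel=0.02)

    def test_translation_equivariance(self):
        base = extract_contour(disk_field(GRID, 5.0), GRID)
        shifted = extract_contour(
            disk_field(GRID, 5.0, center=(GRID.box_size[0] / 2 + 0.9, GRID.box_size[1] / 2 - 0.6)),
            GRID,
        )
        _, disp = map_nodes(base, shifted)
        assert np.allclose(disp, [0.9, -0.6], atol=0.02)

    def test_signals_missing_or_multiple_loops(self):
        with pytest.raises(ContourError):
            extract_contour(np.zeros(GRID.shape), GRID)
        two = np.maximum(
            disk_field(GRID, 3.0, center=(8.0, 8.0)), disk_field(GRID, 3.0, center=(22.0, 22.0))
        )
        with pytest.raises(ContourError):
            extract_contour(two, GRID)


class TestMapNodes:
    def test_identical_contours(self):
        a = circle_contour()
        shift, disp = map_nodes(a, a)
        assert shift == 0
        assert np.allclose(disp, 0.0)

    def test_rigid_translation_recovered(self):
        a = circle_contour()
        b = Contour(a.nodes + [0.1, 0.0])
        _, disp = map_nodes(a, b)
        assert np.allclose(disp, [0.1, 0.0], atol=0.01)

    def test_pure_index_rotation_recovered(self):
        a = circle_contour(phase=0.123)
        s0 = 37
        b = Contour(np.roll(a.nodes, s0, axis=0))
        shift, disp = map_nodes(a, b)
        assert shift == s0
        assert np.allclose(disp, 0.0, atol=1e-12)


class TestLocalDisplacement:
    def test_uniform_expansion(self):
        a, b = circle_contour(6.0), circle_contour(6.1)
        d = local_displacement(a, b)
        assert np.allclose(d, 0.1, atol=1e-6)

    def test_translation_gives_cosine_profile(self):
        a = circle_contour(6.0)
        b = Contour(a.nodes + [0.2, 0.0])
        d = local_displacement(a, b)
        angles = np.arctan2(a.nodes[:, 1], a.nodes[:, 0])
        assert np.allclose(d, 0.2 * np.cos(angles), atol=1e-3)

    def test_stationary_shape_is_zero(self):
        a = circle_contour(4.0, phase=0.3)
        assert np.allclose(local_displacement(a, a), 0.0)


class TestCentroidDistance:
    def test_disk(self):
        assert np.allclose(centroid_distance(circle_contour(6.0)), 6.0, atol=1e-9)

    def test_ellipse_extremes(self):
        phi = ellipse_field(GRID, a=6.0, b=3.0)
        cont = extract_contour(phi, GRID)
        d = centroid_distance(cont)
        assert d.max() == pytest.approx(6.0, rel=0.01)
        assert d.min() == pytest.approx(3.0, rel=0.01)

    def test_translation_invariance(self):
        a = circle_contour(5.0)
        b = Contour(a.nodes + [7.7, -3.1])
        assert np.allclose(centroid_distance(a), centroid_distance(b), atol=1e-9)


class TestLocalCurvature:
    def test_circle_curvature(self):
        k = local_curvature(circle_contour(6.0))
        assert np.allclose(k, 1.0 / 6.0, rtol=0.05)

    def test_turning_number(self):
        # sum of curvature * arc spacing = 2 pi for any simple loop
        for cont in (circle_contour(4.0), extract_contour(ellipse_field(GRID, 6, 3), GRID)):
            ds = cont.perimeter() / cont.n_nodes
            assert np.sum(local_curvature(cont)) * ds == pytest.approx(2 * np.pi, rel=0.01)

    def test_ellipse_extremal_curvatures(self):
        a, b = 6.0, 3.0
        cont = extract_contour(ellipse_field(GRID, a, b), GRID)
        k = local_curvature(cont)
        assert k.max() == pytest.approx(a / b**2, rel=0.05)
        assert k.min() == pytest.approx(b / a**2, rel=0.05)

    def test_rotation_invariance(self):
        c1 = extract_contour(ellipse_field(GRID, 5, 3, angle=0.0), GRID)
        c2 = extract_contour(ellipse_field(GRID, 5, 3, angle=0.7), GRID)
        k1, k2 = np.sort(local_curvature(c1)), np.sort(local_curvature(c2))
        assert np.allclose(k1, k2, atol=0.01)


class TestBoundaryConcentration:
    def test_constant_field(self):
        cont = extract_contour(disk_field(GRID, 5.0), GRID)
        c = np.full(GRID.shape, 3.3)
        assert np.allclose(sample_boundary_concentration(c, cont, GRID), 3.3)

    def test_linear_ramp_gives_sinusoid(self):
        cont = extract_contour(disk_field(GRID, 6.0), GRID)
        x = np.arange(GRID.nx) * GRID.dx
        c = np.tile(x, (GRID.ny, 1))
        vals = sample_boundary_concentration(c, cont, GRID)
        centre = np.array(GRID.box_size) / 2
        rel = cont.nodes - centre
        assert vals[np.argmax(vals)] == pytest.approx(centre[0] + 6.0, abs=0.05)
        assert np.argmax(vals) == pytest.approx(np.argmax(rel[:, 0]), abs=3)
        assert vals[np.argmin(vals)] == pytest.approx(centre[0] - 6.0, abs=0.05)

    def test_half_plane_indicator(self):
        cont = extract_contour(disk_field(GRID, 6.0), GRID)
        yy = np.arange(GRID.ny)[:, None] * GRID.dx * np.ones((1, GRID.nx))
        c = (yy > GRID.box_size[1] / 2).astype(float)
        vals = sample_boundary_concentration(c, cont, GRID)
        upper = cont.nodes[:, 1] > GRID.box_size[1] / 2 + GRID.dx
        lower = cont.nodes[:, 1] < GRID.box_size[1] / 2 - GRID.dx
        assert np.all(vals[upper] > 0.5)
        assert np.all(vals[lower] < 0.5)


class TestKymographs:
    def test_translating_disk_shows_fixed_front_and_back_bands(self):
        snaps = translating_disk_series(GRID, n_frames=10, velocity=(0.12, 0.0))
        kymo = build_kymograph(snaps, "displacement")
        assert kymo.matrix.shape == (400, 9)
        node_mean = kymo.matrix.mean(axis=1)
        # the same nodes stay positive (front) / negative (back) all frames
        front = np.argmax(node_mean)
        back = np.argmin(node_mean)
        assert np.all(kymo.matrix[front] > 0.08)
        assert np.all(kymo.matrix[back] < -0.08)

    def test_stationary_disk_kymographs_are_flat(self):
        frames = [disk_field(GRID, 6.0)] * 5
        snaps = shape_series(frames, GRID)
        disp = build_kymograph(snaps, "displacement").matrix
        dist = build_kymograph(snaps, "centroid_distance").matrix
        assert np.max(np.abs(disp)) < 1e-9
        assert np.allclose(dist, 6.0, atol=GRID.dx)

    def test_expanding_disk_displacement_is_uniformly_positive(self):
        snaps = expanding_disk_series(GRID, n_frames=5, radius0=5.0, growth=0.1)
        kymo = build_kymograph(snaps, "displacement")
        assert np.allclose(kymo.matrix, 0.1, atol=0.02)

    def test_node_tracking_drift_on_translating_fixture(self):
        # chained correspondence on a rigidly translating featured shape:
        # node identity follows the material over 100 frames with less
        # than 2 node spacings of cumulative tangential slippage, despite
        # the arbitrary per-frame start point of the extraction
        from amoeboid.synthetic import bumpy_disk_field

        from amoeboid.contour import align_contours

        Lx, Ly = GRID.box_size
        vel = np.array([0.12, 0.05])  # um per frame
        centres, contours = [], []
        for k in range(100):
            centre = (Lx / 2 - 6 + k * vel[0], Ly / 2 - 3 + k * vel[1])
            phi = bumpy_disk_field(GRID, radius=5.0, amp=0.1, m=1, angle=0.8, center=centre)
            centres.append(centre)
            contours.append(extract_contour(phi, GRID))
        bump_angles = []
        for cont, centre in zip(align_contours(contours), centres):
            rel = cont.nodes[0] - centre
            bump_angles.append(np.arctan2(rel[1], rel[0]))
        bump_angles = np.unwrap(bump_angles)
        # material angle of the tracked node relative to the moving centre
        # must stay constant; 2 node spacings = 2 * 2pi/400 rad
        assert np.ptp(bump_angles) < 2 * (2 * np.pi / 400)

    def test_concentration_kymograph_requires_stored_c(self):
        snaps = translating_disk_series(GRID, n_frames=3)
        with pytest.raises(ValueError):
            build_kymograph(snaps, "concentration")
        with pytest.raises(ValueError):
            build_kymograph(snaps, "windedness")
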