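import numpy as np
import pytest

from mechanoinvade.phantoms import (
    EllipsoidCell,
    InvasionPhantomSpec,
    generate_invasion_stack,
)
from mechanoinvade.qpi import (
    CellContour,
    MembranePlane,
    QpiParams,
    cumulative_invaded_count,
    locate_membrane,
    percent_invasion,
    reconstruct_cell,
    run_qpi,
    segment_slice,
)
from mechanoinvade.stacks import ImageStack
from tests.conftest import sphere_on_plane_spec


def disk_image(center=(64, 64), radius=20, shape=(128, 128), value=1000.0, seed=0):
    rng = np.random.default_rng(seed)
    img = rng.normal(100.0, 5.0, size=shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] += value
    return img


class TestSegmentSlice:
    def test_pure_noise_gives_no_contours(self):
        rng = np.random.default_rng(1)
        img = rng.normal(100.0, 10.0, size=(128, 128))
        assert segment_slice(img) == []

    def test_single_disk_detected_with_correct_geometry(self):
        contours = segment_slice(disk_image())
        assert len(contours) == 1
        pts = contours[0].points
        centroid = pts.mean(axis=0)
        assert np.abs(centroid - 64).max() < 1.0
        # shoelace area of the traced boundary vs true disk area
        x, y = pts[:, 1], pts[:, 0]
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert area == pytest.approx(np.pi * 20**2, rel=0.05)

    def test_two_disjoint_disks_give_two_contours(self):
        img = disk_image(center=(40, 40), radius=15)
        yy, xx = np.mgrid[:128, :128]
        img[(yy - 95) ** 2 + (xx - 95) ** 2 <= 15**2] += 1000.0
        assert len(segment_slice(img)) == 2

    def test_contours_are_counter_clockwise(self):
        pts = segment_slice(disk_image())[0].points
        x, y = pts[:, 1], pts[:, 0]
        assert np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) > 0


class TestLocateMembrane:
    def test_bilayer_returns_upper_layer(self):
        spec = InvasionPhantomSpec(
            cells=(),
            membrane_z_upper_um=2.8,
            membrane_z_lower_um=2.0,
            shape_zyx=(40, 32, 32),
            seed=3,
        )
        stack, _ = generate_invasion_stack(spec)
        assert locate_membrane(stack, "membrane").z_um == pytest.approx(2.8, abs=0.2)

    def test_single_layer(self):
        nz = 50
        prof = 50 + 800 * np.exp(-((np.arange(nz) * 0.2 - 5.0) ** 2) / (2 * 0.15**2))
        data = np.zeros((2, nz, 8, 8))
        data[1] = prof[:, None, None]
        stack = ImageStack(data, (0.2, 0.1, 0.1), ("cell", "membrane"))
        assert locate_membrane(stack, "membrane").z_um == pytest.approx(5.0, abs=0.2)

    def test_blank_channel_errors(self):
        stack = ImageStack(np.zeros((2, 10, 8, 8)), (0.2, 0.1, 0.1), ("cell", "membrane"))
        with pytest.raises(ValueError, match="membrane not detected"):
            locate_membrane(stack, "membrane")


def sphere_contours(radius_um=5.0, dz=0.2, dxy=0.1, n_pts=72):
    """Circles sampled from a sphere at each z-slice, as CellContour objects."""
    contours = []
    n_slices = int(2 * radius_um / dz) + 1
    for k in range(n_slices):
        z = k * dz - radius_um
        r2 = radius_um**2 - z**2
        if r2 <= 0:
            continue
        r_px = np.sqrt(r2) / dxy
        t = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
        pts = np.column_stack([100 + r_px * np.sin(t), 100 + r_px * np.cos(t)])
        contours.append(CellContour(k, pts, np.arange(n_pts)))
    return contours


class TestReconstructCell:
    def test_sphere_volume_recovered(self):
        cell = reconstruct_cell(sphere_contours(), (0.2, 0.1, 0.1))
        true_vol = 4 / 3 * np.pi * 125
        assert cell.volume_um3 == pytest.approx(true_vol, rel=0.02)

    def test_volume_scales_linearly_with_z_step(self):
        contours = sphere_contours()
        v1 = reconstruct_cell(contours, (0.2, 0.1, 0.1)).volume_um3
        v2 = reconstruct_cell(contours, (0.4, 0.1, 0.1)).volume_um3
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_single_slice_errors(self):
        contours = [c for c in sphere_contours() if c.slice_index == 25]
        with pytest.raises(ValueError, match="z-extent"):
            reconstruct_cell(contours, (0.2, 0.1, 0.1))

    def test_hull_contains_all_source_points(self):
        from scipy.spatial import ConvexHull

        cell = reconstruct_cell(sphere_contours(n_pts=24), (0.2, 0.1, 0.1))
        hull = ConvexHull(cell.vertices_um)
        A, b = hull.equations[:, :3], hull.equations[:, 3]
        assert (cell.points_um @ A.T + b <= 1e-8).all()


class TestPercentInvasion:
    def test_plane_extremes(self):
        cell = reconstruct_cell(sphere_contours(), (0.2, 0.1, 0.1))
        zmin = cell.vertices_um[:, 2].min()
        zmax = cell.vertices_um[:, 2].max()
        assert percent_invasion(cell, MembranePlane(zmin - 1, 0)).percent_below == 0.0
        assert percent_invasion(cell, MembranePlane(zmax + 1, 0)).percent_below == 100.0

    def test_spherical_cap_value(self):
        """Plane r/2 below the sphere centre: 15.625% below."""
        cell = reconstruct_cell(sphere_contours(radius_um=5.0), (0.2, 0.1, 0.1))
        z_center = 5.0  # slices span z = 0..2r
        res = percent_invasion(cell, MembranePlane(z_center - 2.5, 0))
        assert res.percent_below == pytest.approx(15.625, abs=0.3)


class TestRunQpi:
    def test_hemisphere_phantom_near_fifty(self):
        stack, truth = generate_invasion_stack(sphere_on_plane_spec())
        results, skipped, hulls = run_qpi(stack)
        assert len(results) == 1 and not skipped
        assert results[0].percent_below == pytest.approx(50.0, abs=1.5)
        assert results[0].volume_um3 == pytest.approx(truth.volume_um3[0], rel=0.05)

    def test_cell_above_membrane_reports_low_invasion(self):
        stack, truth = generate_invasion_stack(
            sphere_on_plane_spec(radius_um=2.5, offset_um=3.6, seed=2)
        )
        assert truth.percent_below[0] == 0.0
        results, _, _ = run_qpi(stack)
        assert len(results) == 1
        assert results[0].percent_below < 3.0

    def test_empty_cell_channel_gives_no_results(self):
        spec = InvasionPhantomSpec(
            cells=(),
            membrane_z_upper_um=3.0,
            membrane_z_lower_um=2.2,
            shape_zyx=(30, 64, 64),
            seed=4,
        )
        stack, _ = generate_invasion_stack(spec)
        results, skipped, hulls = run_qpi(stack)
        assert results == [] and hulls == {}

    def test_border_touching_cell_skipped(self):
        # block of signal abutting the y = 0 image edge: its hull volume
        # would be truncated, so it must be excluded by default
        data = np.zeros((2, 40, 64, 64))
        data[0, 10:30, 0:20, 25:45] = 1000.0
        data[1, 25] = 800.0  # membrane plane at z index 25
        stack = ImageStack(data, (0.2, 0.15, 0.15), ("cell", "membrane"))
        results, skipped, _ = run_qpi(stack)
        assert results == []
        assert any("border" in rec["reason"] for rec in skipped)
        kept, _, _ = run_qpi(stack, params=QpiParams(exclude_border=False))
        assert len(kept) == 1


class TestCumulativeCount:
    def test_running_sum_of_daily_means(self):
        out = cumulative_invaded_count([np.array([2.0]), np.array([3.0])], [1, 1])
        np.testing.assert_allclose(out.cumulative_mean, [2.0, 5.0])

    def test_normalised_by_mesentery_count(self):
        out = cumulative_invaded_count([np.array([4.0, 4.0])] * 2, [2, 2])
        np.testing.assert_allclose(out.daily_mean, [2.0, 2.0])

    def test_errors_summed_not_in_quadrature(self):
        counts = [np.array([1.0, 2.0, 3.0])] * 2  # sem = 1/sqrt(3) each day
        out = cumulative_invaded_count(counts, [1, 1])
        sem = np.std(counts[0], ddof=1) / np.sqrt(3)
        np.testing.assert_allclose(out.cumulative_sem, [sem, 2 * sem])

    def test_zero_mesenteries_rejected(self):
        with pytest.raises(ValueError, match="mesentery"):
            cumulative_invaded_count([np.array([1.0])], [0])
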