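"""DICOM round-trips and isocenter plane/surface extraction."""

import numpy as np
import pydicom
import pytest

from vmatqa.errors import FormatError, GeometryError, ParameterError, UnsupportedPlanError
from vmatqa.rtplan_io import (
    DoseGrid,
    extract_isocenter_planes,
    extract_surface_dose,
    read_rtdose,
    read_rtplan,
    write_rtdose,
    write_rtplan,
)
from vmatqa.synthetic import PlanGenParams, generate_plan


class TestRtPlanRoundTrip:
    def test_synthetic_plan_round_trips_field_by_field(self, tmp_path):
        plan = generate_plan(PlanGenParams(n_control_points=178, seed=5))
        path = tmp_path / "plan.dcm"
        write_rtplan(plan, path)
        back = read_rtplan(path)
        assert back.n_control_points == 178
        assert back.plan_id == plan.plan_id
        np.testing.assert_allclose(back.isocenter, plan.isocenter)
        assert back.prescription_dose == pytest.approx(plan.prescription_dose)
        for cp, cp2 in zip(plan.control_points, back.control_points):
            assert cp2.index == cp.index
            assert cp2.gantry_angle == pytest.approx(cp.gantry_angle % 360.0)
            assert cp2.meterset_weight == pytest.approx(cp.meterset_weight)
            np.testing.assert_allclose(cp2.bank_a, cp.bank_a)
            np.testing.assert_allclose(cp2.bank_b, cp.bank_b)

    def test_closed_plan_reads_back_with_zero_gaps(self, tmp_path, closed_plan):
        path = tmp_path / "closed.dcm"
        write_rtplan(closed_plan, path)
        back = read_rtplan(path)
        for cp in back.control_points:
            np.testing.assert_allclose(cp.gaps, 0.0, atol=1e-9)

    def test_non_monotone_meterset_rejected(self, tmp_path, closed_plan):
        path = tmp_path / "bad.dcm"
        write_rtplan(closed_plan, path)
        ds = pydicom.dcmread(path)
        cps = ds.BeamSequence[0].ControlPointSequence
        cps[0].CumulativeMetersetWeight = 0.9
        cps[1].CumulativeMetersetWeight = 0.1
        ds.save_as(path, enforce_file_format=True)
        with pytest.raises(FormatError):
            read_rtplan(path)

    def test_multi_beam_plan_unsupported(self, tmp_path, closed_plan):
        path = tmp_path / "twobeam.dcm"
        write_rtplan(closed_plan, path)
        ds = pydicom.dcmread(path)
        ds.BeamSequence.append(ds.BeamSequence[0])
        ds.save_as(path, enforce_file_format=True)
        with pytest.raises(UnsupportedPlanError):
            read_rtplan(path)

    def test_missing_mlc_positions_is_format_error(self, tmp_path, closed_plan):
        path = tmp_path / "nomlc.dcm"
        write_rtplan(closed_plan, path)
        ds = pydicom.dcmread(path)
        del ds.BeamSequence[0].ControlPointSequence[0].BeamLimitingDevicePositionSequence
        ds.save_as(path, enforce_file_format=True)
        with pytest.raises(FormatError):
            read_rtplan(path)


class TestRtDose:
    def test_grid_scaling_applied(self, tmp_path):
        grid = DoseGrid(values=np.ones((4, 5, 6)) * 0.01, origin=np.zeros(3),
                        spacing=np.full(3, 2.0))
        path = tmp_path / "dose.dcm"
        write_rtdose(grid, path, dose_grid_scaling=0.01)
        back = read_rtdose(path)
        np.testing.assert_allclose(back.values, 0.01)
        np.testing.assert_allclose(back.spacing, [2.0, 2.0, 2.0])

    def test_round_trip_is_bitwise_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        scaling = 1e-4  # integer-multiple doses round-trip exactly
        values = rng.integers(0, 70000, size=(8, 9, 10)).astype(float) * scaling
        grid = DoseGrid(values=values, origin=np.array([-8.0, -9.0, -10.0]),
                        spacing=np.full(3, 2.0))
        path = tmp_path / "dose.dcm"
        write_rtdose(grid, path, dose_grid_scaling=scaling)
        back = read_rtdose(path)
        assert np.array_equal(back.values, grid.values)
        np.testing.assert_allclose(back.origin, grid.origin)

    def test_missing_scaling_is_format_error(self, tmp_path):
        grid = DoseGrid(values=np.ones((3, 3, 3)), origin=np.zeros(3), spacing=np.full(3, 2.0))
        path = tmp_path / "dose.dcm"
        write_rtdose(grid, path)
        ds = pydicom.dcmread(path)
        del ds.DoseGridScaling
        ds.save_as(path, enforce_file_format=True)
        with pytest.raises(FormatError):
            read_rtdose(path)


def _centered_grid(shape, spacing=2.0):
    shape = np.asarray(shape)
    origin = -(shape - 1) / 2.0 * spacing
    return origin


class TestPlaneExtraction:
    SHAPES = {"sagittal": (68, 146), "coronal": (64, 200), "axial": (143, 242)}

    def test_uniform_grid_gives_constant_planes_at_target_shapes(self):
        values = np.full((80, 80, 80), 3.5)
        origin = _centered_grid((80, 80, 80))
        grid = DoseGrid(values=values, origin=origin, spacing=np.full(3, 2.0))
        planes = extract_isocenter_planes(grid, np.zeros(3), self.SHAPES)
        for name, shape in self.SHAPES.items():
            img = getattr(planes, name)
            assert img.shape == shape
            # zero padding appears where the target exceeds the grid
            center = img[shape[0] // 2, shape[1] // 2]
            assert center == 3.5

    def test_delta_dose_maps_to_center_pixel(self):
        values = np.zeros((40, 40, 40))
        values[20, 20, 20] = 1.0
        origin = _centered_grid((40, 40, 40))
        # isocenter exactly at voxel (20, 20, 20)
        iso = origin + 20 * 2.0
        grid = DoseGrid(values=values, origin=origin, spacing=np.full(3, 2.0))
        planes = extract_isocenter_planes(grid, iso, self.SHAPES)
        for name, shape in self.SHAPES.items():
            img = getattr(planes, name)
            r, c = np.unravel_index(np.argmax(img), img.shape)
            assert (r, c) == (shape[0] // 2, shape[1] // 2)
            assert img[r, c] == 1.0

    def test_small_grid_zero_padded_with_values_preserved(self):
        rng = np.random.default_rng(3)
        values = rng.random((9, 9, 9))  # odd grid: isocenter on voxel (4,4,4)
        origin = _centered_grid((9, 9, 9))
        grid = DoseGrid(values=values, origin=origin, spacing=np.full(3, 2.0))
        planes = extract_isocenter_planes(grid, np.zeros(3), {"sagittal": (20, 30),
                                                              "coronal": (20, 30),
                                                              "axial": (20, 30)})
        sag = planes.sagittal
        # the 9x9 slice lands with voxel (4,4) on the output center (10,15)
        inner = sag[10 - 4 : 10 + 5, 15 - 4 : 15 + 5]
        np.testing.assert_array_equal(inner, values[4, :, :])
        assert sag.sum() == pytest.approx(inner.sum())

    def test_output_shape_invariant_to_grid_size(self):
        for n in (20, 50, 90):
            values = np.ones((n, n, n))
            grid = DoseGrid(values=values, origin=_centered_grid((n, n, n)),
                            spacing=np.full(3, 2.0))
            planes = extract_isocenter_planes(grid, np.zeros(3), self.SHAPES)
            for name, shape in self.SHAPES.items():
                assert getattr(planes, name).shape == shape

    def test_isocenter_outside_grid_raises(self):
        grid = DoseGrid(values=np.ones((10, 10, 10)), origin=_centered_grid((10, 10, 10)),
                        spacing=np.full(3, 2.0))
        with pytest.raises(GeometryError):
            extract_isocenter_planes(grid, np.array([500.0, 0.0, 0.0]), self.SHAPES)


class TestSurfaceDose:
    def test_uniform_grid_gives_constant_map(self):
        grid = DoseGrid(values=np.full((60, 60, 60), 2.0),
                        origin=_centered_grid((60, 60, 60)), spacing=np.full(3, 2.0))
        surf = extract_surface_dose(grid, np.zeros(3), radius=30.0, n_angles=90, n_axial=40)
        assert surf.shape == (40, 90)
        np.testing.assert_allclose(surf, 2.0)

    def test_radially_symmetric_dose_constant_along_azimuth(self):
        n = 61
        origin = _centered_grid((n, n, n))
        x = origin[0] + np.arange(n) * 2.0
        xx, yy = np.meshgrid(x, x, indexing="ij")
        r2 = xx**2 + yy**2
        values = np.repeat((100.0 - 1e-3 * r2)[:, :, None], n, axis=2)
        grid = DoseGrid(values=values, origin=origin, spacing=np.full(3, 2.0))
        surf = extract_surface_dose(grid, np.zeros(3), radius=25.0, n_angles=120, n_axial=10)
        # trilinear interpolation of a smooth radial field: tiny azimuthal ripple only
        assert np.ptp(surf, axis=1).max() < 1e-2

    def test_cylinder_outside_grid_samples_zero(self):
        grid = DoseGrid(values=np.ones((20, 20, 20)), origin=_centered_grid((20, 20, 20)),
                        spacing=np.full(3, 2.0))
        surf = extract_surface_dose(grid, np.zeros(3), radius=500.0, n_angles=36, n_axial=8)
        np.testing.assert_array_equal(surf, 0.0)

    def test_non_positive_radius_rejected(self):
        grid = DoseGrid(values=np.ones((10, 10, 10)), origin=_centered_grid((10, 10, 10)),
                        spacing=np.full(3, 2.0))
        with pytest.raises(ParameterError):
            extract_surface_dose(grid, np.zeros(3), radius=0.0)
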