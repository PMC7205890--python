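"""Volume curve, global indices, wall thickness/thickening, sectors, GGMRF."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from cinestrain import (
    ClosedContour,
    SectorModel,
    SegmentationStack,
    UndefinedTermError,
    assign_sectors,
    ggmrf_smooth,
    global_indices,
    lv_volume_curve,
    sectors_at_level,
    thickening_table,
    wall_thickening,
    wall_thickness,
)
from cinestrain.ventriculo import ThicknessMap
from conftest import circle_contour


def stack_with_counts(cavity_counts, myo_counts=None, pixel_area=1.0,
                      slice_spacing=1.0, size=32):
    """Stack whose (slice, frame) cavity/myocardium pixel counts are given."""
    cavity_counts = np.atleast_2d(cavity_counts)  # (S, T)
    S, T = cavity_counts.shape
    myo_counts = np.zeros((S, T), int) if myo_counts is None else np.atleast_2d(myo_counts)
    masks = np.zeros((S, T, size, size), np.uint8)
    for s in range(S):
        for t in range(T):
            flat = masks[s, t].ravel()
            n_c, n_m = int(cavity_counts[s, t]), int(myo_counts[s, t])
            flat[:n_c] = 1
            flat[n_c:n_c + n_m] = 2
    return SegmentationStack(masks, pixel_area=pixel_area, slice_spacing=slice_spacing)


class TestVolumes:
    def test_three_slice_summation(self):
        """Cavity areas 2, 3, 4 mm^2 at 1 mm slice spacing give 9 uL."""
        stack = stack_with_counts([[2], [3], [4]])
        curve = lv_volume_curve(stack)
        assert curve.volumes[0] == pytest.approx(9.0)

    def test_all_empty_masks_zero_curve(self):
        stack = stack_with_counts(np.zeros((2, 3), int))
        curve = lv_volume_curve(stack)
        assert np.all(curve.volumes == 0.0)

    def test_ed_es_are_extremes_earliest_on_ties(self):
        stack = stack_with_counts([[5, 9, 3, 9, 3]])
        curve = lv_volume_curve(stack)
        assert curve.t_ed == 1 and curve.t_es == 2
        assert curve.volumes[curve.t_ed] == curve.volumes.max()
        assert curve.volumes[curve.t_es] == curve.volumes.min()

    def test_volume_additivity_over_slices(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(4, 6))
        full = lv_volume_curve(stack_with_counts(counts)).volumes
        a = lv_volume_curve(stack_with_counts(counts[:2])).volumes
        b = lv_volume_curve(stack_with_counts(counts[2:])).volumes
        assert np.array_equal(full, a + b)

    def test_phantom_cavity_volume_matches_analytic(self, compression_run):
        spec, seq, _ = compression_run
        stack = seq.segmentation_stack()
        curve = lv_volume_curve(stack)
        for t in range(spec.n_frames):
            lam = 1 + (spec.lambda_min - 1) * spec.amplitude(t + 1)
            analytic = np.pi * (lam * spec.r_endo) ** 2 * stack.slice_spacing
            assert curve.volumes[t] == pytest.approx(analytic, rel=0.02)


class TestGlobalIndices:
    def test_density_scaling_one_cc(self):
        """1 cm^3 of myocardium at end diastole weighs exactly 1.05 g."""
        stack = stack_with_counts([[10, 4]], [[100, 100]],
                                  pixel_area=1.0, slice_spacing=10.0)
        gi = global_indices(stack)
        assert gi.lvm == 1.05

    def test_sv_ef_arithmetic(self):
        stack = stack_with_counts([[50, 20]])  # pixel_area x spacing = 1 uL
        gi = global_indices(stack)
        assert gi.edv == 50 and gi.esv == 20
        assert gi.sv == pytest.approx(30.0)
        assert gi.ef == pytest.approx(60.0)

    def test_identical_frames_zero_sv(self):
        stack = stack_with_counts([[30, 30, 30]], [[10, 10, 10]])
        gi = global_indices(stack)
        assert gi.sv == 0.0 and gi.ef == 0.0

    def test_empty_cavity_rejected(self):
        stack = stack_with_counts([[0, 0]], [[5, 5]])
        with pytest.raises(UndefinedTermError):
            global_indices(stack)

    def test_ef_invariant_to_pixel_area(self):
        a = global_indices(stack_with_counts([[40, 10]], pixel_area=1.0))
        b = global_indices(stack_with_counts([[40, 10]], pixel_area=0.01))
        assert a.ef == pytest.approx(b.ef)

    def test_lvm_linear_in_density(self):
        stack = stack_with_counts([[10, 10]], [[200, 200]])
        assert global_indices(stack, density=2.1).lvm == pytest.approx(
            2 * global_indices(stack, density=1.05).lvm
        )

    def test_normalization_by_body_mass(self):
        stack = stack_with_counts([[50, 20]], [[100, 100]])
        gi = global_indices(stack, body_mass=25.0)
        assert gi.svi == pytest.approx(gi.sv / 25.0)
        assert gi.lvm_normalized == pytest.approx(gi.lvm / 25.0)


class TestWallThickness:
    def test_concentric_annulus_thickness(self):
        """2 mm / 3 mm concentric circles: thickness 1 mm within 3%."""
        spacing = 0.05  # mm/px -> radii 40 and 60 px
        endo = circle_contour(40)
        epi = circle_contour(60)
        tm = wall_thickness(endo, epi, n_points=36, spacing=spacing)
        assert np.allclose(tm.thickness, 1.0, rtol=0.03)
        assert not tm.degenerate

    def test_uniform_dilation_thickness(self):
        """Epicardium = endocardium dilated by 5 px: thickness 5 px with
        low spread, even for a non-circular wall."""
        th = np.linspace(0, 2 * np.pi, 180, endpoint=False)
        pts = np.column_stack([64 + 22 * np.cos(th), 64 + 15 * np.sin(th)])
        endo = ClosedContour(pts)
        dilated = Polygon(pts).buffer(5.0, quad_segs=64)
        epi = ClosedContour(np.asarray(dilated.exterior.coords)[:-1])
        tm = wall_thickness(endo, epi, n_points=72)
        assert tm.thickness.mean() == pytest.approx(5.0, rel=0.03)
        assert tm.thickness.std() / tm.thickness.mean() < 0.05

    def test_identical_contours_degenerate(self):
        tm = wall_thickness(circle_contour(20), circle_contour(20), n_points=24)
        assert tm.degenerate
        assert np.allclose(tm.thickness, 0.0)


class TestSectors:
    def test_binning_convention(self):
        c = (0.0, 0.0)
        pt = np.array([[np.cos(np.pi / 6), np.sin(np.pi / 6)]])  # ref + 30 deg
        assert assign_sectors(pt, c, "basal", reference_angle=0.0)[0] == 1

    def test_uniform_points_fill_sectors_evenly(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        ids = assign_sectors(pts, (0, 0), "basal")
        counts = np.bincount(ids)[1:7]
        assert np.all(counts == 60)

    def test_level_sector_ids(self):
        assert sectors_at_level("basal") == (1, 2, 3, 4, 5, 6)
        assert sectors_at_level("mid-cavity") == (7, 8, 9, 10, 11, 12)
        assert sectors_at_level("apical") == (13, 14, 15, 16)
        with pytest.raises(ValueError):
            sectors_at_level("apex")
        th = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        assert set(assign_sectors(pts, (0, 0), "apical")) == {13, 14, 15, 16}

    def test_default_slice_level_mapping(self):
        model = SectorModel.default_for(8)
        assert model.levels == ("basal",) * 3 + ("mid-cavity",) * 3 + ("apical",) * 2


class TestThickening:
    def _map(self, values, radius=10.0):
        th = np.linspace(0, 2 * np.pi, len(values), endpoint=False)
        pts = np.column_stack([radius * np.cos(th), radius * np.sin(th)])
        return ThicknessMap(points=pts, thickness=np.asarray(values, float))

    def test_no_change_gives_zero(self):
        ed = self._map(np.full(60, 2.0))
        out = wall_thickening(ed, self._map(np.full(60, 2.0)), "basal")
        assert all(v == 0.0 for v in out.values())

    def test_uniform_scaling(self):
        ed = self._map(np.full(60, 2.0))
        es = self._map(np.full(60, 3.0))
        out = wall_thickening(ed, es, "basal")
        assert all(v == pytest.approx(0.5) for v in out.values())

    def test_wedge_thickening_localized(self):
        th = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        ed_vals = np.full(120, 1.0)
        es_vals = np.where(th < np.pi / 3, 1.5, 1.0)  # sector 1 thickens
        out = wall_thickening(self._map(ed_vals), self._map(es_vals), "basal")
        assert out[1] > 0.1
        assert all(abs(out[s]) < 0.01 for s in range(2, 7))

    def test_zero_ed_points_excluded(self):
        ed = self._map(np.concatenate([[0.0], np.full(59, 2.0)]))
        es = self._map(np.full(60, 3.0))
        out = wall_thickening(ed, es, "basal")
        assert np.isfinite(list(out.values())).all()

    def test_table_has_sixteen_segments(self):
        model = SectorModel.default_for(8)
        per_slice = []
        for level in model.levels:
            vals = self._map(np.full(60, 1.0))
            per_slice.append(wall_thickening(vals, self._map(np.full(60, 1.2)), level))
        table = thickening_table(per_slice, model)
        assert sorted(table) == list(range(1, 17))
        assert all(np.isfinite(v) for v in table.values())


class TestGGMRF:
    def test_zero_gamma_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=24)
        assert np.array_equal(ggmrf_smooth(x, gamma=0.0), x)

    def test_constant_input_unchanged(self):
        x = np.full(30, 3.3)
        for p in (1.2, 2.0):
            assert np.allclose(ggmrf_smooth(x, p=p, gamma=2.0), x, atol=1e-8)

    def test_quadratic_case_matches_dense_oracle(self):
        """p = 2 on a 12-point ring equals the dense normal-equations
        solution (I + gamma^2 L) x = d."""
        rng = np.random.default_rng(1)
        d = rng.normal(size=12)
        gamma = 1.5
        n = 12
        lap = np.zeros((n, n))
        for i in range(n):
            lap[i, i] = 2.0
            lap[i, (i + 1) % n] -= 1.0
            lap[i, (i - 1) % n] -= 1.0
        oracle = np.linalg.solve(np.eye(n) + gamma**2 * lap, d)
        assert np.allclose(ggmrf_smooth(d, p=2.0, gamma=gamma), oracle, atol=1e-9)

    def test_spike_is_shrunk(self):
        flat = np.zeros(12)
        flat[0] = 5.0
        for p in (2.0, 1.3):
            out = ggmrf_smooth(flat, p=p, gamma=1.0)
            assert abs(out[0]) < 5.0
            assert np.abs(out).max() <= 5.0

    def test_objective_never_increases(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=(3, 20))  # 3 slices, ring of 20
        p, gamma = 1.5, 1.0
        out = ggmrf_smooth(d, p=p, gamma=gamma)

        def energy(x):
            e = np.sum(np.abs(x - d) ** p)
            e += gamma**p * np.sum(np.abs(x - np.roll(x, 1, axis=1)) ** p)
            e += gamma**p * np.sum(np.abs(np.diff(x, axis=0)) ** p)
            return e

        assert energy(out) <= energy(d)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ggmrf_smooth(np.zeros(5), p=2.5)
        with pytest.raises(ValueError):
            ggmrf_smooth(np.zeros(5), gamma=-1.0)
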