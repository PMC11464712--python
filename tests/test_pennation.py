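"""Pennation-angle geometry: tendon direction, projection algebra, ROI stats."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pennadti import (
    PhantomSpec,
    compute_pa_map,
    fit_tendon_direction,
    fit_tensor,
    generate_phantom,
    pennation_angle,
    summarize_rois,
)
from pennadti.io import ROILabelMap, TendonAnnotation
from pennadti.pennation import PAMap

EZ = np.array([0.0, 0.0, 1.0])
EX = np.array([1.0, 0.0, 0.0])


class TestTendonDirection:
    def test_collinear_vertices_give_the_axis(self):
        affine = np.diag([0.75, 0.75, 3.0, 1.0])
        t = fit_tendon_direction(np.array([[5, 9], [20, 9], [40, 9]]), affine)
        assert t == pytest.approx([1, 0, 0])

    def test_symmetric_zigzag_about_diagonal(self):
        """TLS line through a zig-zag mirrored about the 45-degree diagonal."""
        affine = np.eye(4)
        # mirror-pairs about the diagonal: reflection symmetry forces the
        # TLS axis onto the 45-degree line
        verts = np.array([[0, 1], [1, 0], [3, 4], [4, 3], [6, 7], [7, 6]], float)
        t = fit_tendon_direction(verts, affine)
        assert t == pytest.approx([np.sqrt(0.5), np.sqrt(0.5), 0], abs=1e-12)

    def test_noisy_vertices_recover_generating_line(self, rng):
        angle = np.radians(30.0)
        line = np.array([np.cos(angle), np.sin(angle)])
        pts = np.linspace(0, 40, 5)[:, None] * line
        pts += rng.normal(0, 0.2, pts.shape)
        t = fit_tendon_direction(pts, np.eye(4))
        recovered = math.degrees(math.atan2(t[1], t[0]))
        assert abs(recovered - 30.0) < 2.0

    def test_coincident_vertices_rejected(self):
        with pytest.raises(ValueError, match="distinct|coincide"):
            fit_tendon_direction(np.array([[3.0, 3.0], [3.0, 3.0]]), np.eye(4))

    def test_direction_is_in_plane_for_oblique_affine(self):
        affine = np.eye(4)
        affine[:3, :3] = np.array([[0.7, 0.1, 0.0],
                                   [0.1, 0.8, 0.2],
                                   [0.0, 0.1, 3.0]])
        t = fit_tendon_direction(np.array([[0, 0], [10, 4]]), affine)
        u, v = affine[:3, 0], affine[:3, 1]
        n = np.cross(u, v)
        n /= np.linalg.norm(n)
        assert abs(t @ n) < 1e-10
        assert np.linalg.norm(t) == pytest.approx(1.0)


class TestPennationAngle:
    @pytest.mark.parametrize("v, expected", [
        (EX, 0.0),                                  # parallel to tendon
        (-EX, 0.0),                                 # fibers are axial
        ([0, 1, 0], 90.0),                          # in-plane perpendicular
        (np.array([1, 1, 1]) / np.sqrt(3), 45.0),   # equal in-plane components
    ])
    def test_closed_form_cases(self, v, expected):
        assert pennation_angle(np.asarray(v, float), EX, EZ) == pytest.approx(
            expected, abs=1e-10)

    def test_through_plane_fiber_is_nan(self):
        assert math.isnan(pennation_angle(EZ, EX, EZ))

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            pennation_angle(2.0 * EX, EX, EZ)
        with pytest.raises(ValueError, match="perpendicular"):
            pennation_angle(EX, EX, EX)

    def test_matches_analytic_angle_on_dense_grid(self):
        """For in-plane fibers the PA equals the plain angle between
        directions over the whole [0, 90] range."""
        angles = np.linspace(0.0, 90.0, 1801)
        for a in angles:
            v = np.array([np.cos(np.radians(a)), np.sin(np.radians(a)), 0.0])
            assert abs(pennation_angle(v, EX, EZ) - a) < 1e-10

    def test_elevation_is_removed_by_projection(self):
        """Out-of-plane elevation does not change the in-plane angle."""
        az, el = np.radians(10.0), np.radians(30.0)
        v = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
        assert pennation_angle(v, EX, EZ) == pytest.approx(10.0, abs=1e-10)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(azimuth=st.floats(0, 360), elevation=st.floats(-80, 80),
           rotation=st.floats(0, 360))
    def test_invariance_under_joint_rotation_and_sign_flip(
            self, azimuth, elevation, rotation):
        """PA is unchanged by flipping v and by rotating v and T together
        about the plane normal."""
        az, el, rot = map(np.radians, (azimuth, elevation, rotation))
        v = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
        c, s = np.cos(rot), np.sin(rot)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        pa0 = pennation_angle(v, EX, EZ)
        assert pennation_angle(-v, EX, EZ) == pytest.approx(pa0, abs=1e-8)
        assert pennation_angle(R @ v, R @ EX, EZ) == pytest.approx(pa0, abs=1e-8)
        # flipping the out-of-plane component changes nothing in-plane
        v_flip = v * np.array([1, 1, -1])
        assert pennation_angle(v_flip, EX, EZ) == pytest.approx(pa0, abs=1e-8)


class TestPAMap:
    def test_uniform_field_gives_constant_map(self):
        """All fibers at 20 degrees in-plane to the tendon -> PA 20
        everywhere (noiseless phantom, anterior band only)."""
        spec = PhantomSpec(shape=(24, 32, 3), anterior_pa=20.0, posterior_pa=20.0)
        stack, table, truth = generate_phantom(spec)
        field = fit_tensor(stack, table, mask=truth.muscle_mask)
        pa = compute_pa_map(field, truth.annotation, mask=truth.rois.labels > 0)
        finite = pa.pa[np.isfinite(pa.pa)]
        assert finite.size > 0
        assert np.abs(finite - 20.0).max() < 1e-6

    def test_out_of_plane_elevation_does_not_bias_map(self):
        spec = PhantomSpec(shape=(24, 32, 3), anterior_pa=10.0,
                           anterior_elevation=30.0)
        stack, table, truth = generate_phantom(spec)
        field = fit_tensor(stack, table, mask=truth.muscle_mask)
        pa = compute_pa_map(field, truth.annotation, mask=truth.rois.labels == 1)
        finite = pa.pa[np.isfinite(pa.pa)]
        assert np.abs(finite - 10.0).max() < 1e-6

    def test_slice_outside_volume_rejected(self, small_phantom, small_field):
        _, _, truth = small_phantom
        ann = TendonAnnotation(slice_index=99, vertices=truth.annotation.vertices,
                               direction=truth.annotation.direction)
        with pytest.raises(ValueError, match="outside"):
            compute_pa_map(small_field, ann)

    def test_empty_mask_warns_and_returns_all_nan(self, small_phantom, small_field):
        _, _, truth = small_phantom
        with pytest.warns(UserWarning, match="all NaN"):
            pa = compute_pa_map(small_field, truth.annotation,
                                mask=np.zeros_like(truth.muscle_mask))
        assert np.isnan(pa.pa).all()

    def test_pa_map_range_invariant(self, small_phantom, small_field):
        _, _, truth = small_phantom
        pa = compute_pa_map(small_field, truth.annotation, mask=truth.muscle_mask)
        finite = pa.pa[np.isfinite(pa.pa)]
        assert finite.min() >= 0.0 and finite.max() <= 90.0
        assert abs(pa.tendon_direction @ pa.plane_normal) < 1e-6


class TestROISummary:
    def test_uniform_map_any_roi(self):
        pa = PAMap(slice_index=0, slice_axis=2, pa=np.full((8, 8), 20.0),
                   tendon_direction=EX, plane_normal=EZ)
        labels = np.zeros((8, 8, 1), dtype=np.int16)
        labels[1:5, 1:5, 0] = 3
        s = summarize_rois(pa, ROILabelMap(labels=labels))
        assert s.loc[0, "mean"] == pytest.approx(20.0)
        assert s.loc[0, "sd"] == pytest.approx(0.0)
        assert s.loc[0, "n"] == 16

    def test_bipennate_phantom_roi_means(self, small_phantom, small_field):
        _, _, truth = small_phantom
        pa = compute_pa_map(small_field, truth.annotation, mask=truth.muscle_mask)
        s = summarize_rois(pa, truth.rois).set_index("label")
        assert s.loc[1, "mean"] == pytest.approx(16.0, abs=0.1)
        assert s.loc[2, "mean"] == pytest.approx(11.0, abs=0.1)

    def test_all_nan_roi_dropped_with_warning(self):
        grid = np.full((8, 8), np.nan)
        grid[:2] = 15.0
        pa = PAMap(slice_index=0, slice_axis=2, pa=grid,
                   tendon_direction=EX, plane_normal=EZ)
        labels = np.zeros((8, 8, 1), dtype=np.int16)
        labels[:2, :, 0] = 1
        labels[5:, :, 0] = 2  # overlaps only NaN
        with pytest.warns(UserWarning, match="label 2"):
            s = summarize_rois(pa, ROILabelMap(labels=labels))
        assert s["label"].tolist() == [1]
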