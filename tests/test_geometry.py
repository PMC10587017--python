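"""Geometric primitives: plane fitting, axial resampling, centres of volume."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spinemorph import (LabelledVolume, Plane3D, centre_of_volume,
                        fit_endplate_plane, resample_true_axial)

from conftest import brute_force_cov


def _rot(axis, deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.cos(a) * np.eye(3) + np.sin(a) * k + \
        (1 - np.cos(a)) * np.outer(axis, axis)


def _plane_points(n=200, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.zeros((n, 3))
    pts[:, 0] = rng.uniform(-15, 15, n)
    pts[:, 1] = rng.uniform(-10, 10, n)
    return pts


class TestFitEndplatePlane:
    def test_horizontal_plane_is_recovered_exactly(self):
        pts = _plane_points()
        pts[:, 2] = 5.0
        plane = fit_endplate_plane(pts)
        assert np.allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert plane.centre[2] == pytest.approx(5.0)

    def test_tilted_jittered_plane_within_one_degree(self):
        rng = np.random.default_rng(42)
        pts = _plane_points(seed=1) @ _rot([1, 0, 0], 10).T
        pts += rng.normal(0, 0.3, pts.shape)   # 0.3 mm isotropic jitter
        plane = fit_endplate_plane(pts)
        truth = _rot([1, 0, 0], 10) @ np.array([0, 0, 1.0])
        ang = np.degrees(np.arccos(np.clip(plane.normal @ truth, -1, 1)))
        assert ang < 1.0

    @pytest.mark.parametrize("pts", [
        np.array([[0.0, 0, 0], [1, 1, 1]]),                       # 2 points
        np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),  # collinear
    ])
    def test_degenerate_inputs_raise(self, pts):
        with pytest.raises(ValueError):
            fit_endplate_plane(pts)

    def test_isotropic_cloud_rejected(self):
        # cube corners have an exactly isotropic covariance: the
        # least-variance direction is undefined
        cube = np.array([[i, j, k] for i in (-1, 1) for j in (-1, 1)
                         for k in (-1, 1)], dtype=float)
        with pytest.raises(ValueError, match="ambiguous|isotropic"):
            fit_endplate_plane(cube)

    @given(st.floats(-60, 60), st.floats(-60, 60), st.floats(-180, 180))
    def test_rotation_equivariance(self, ax, ay, az):
        pts = _plane_points(seed=3)
        pts[:, 2] += 0.05 * pts[:, 0]  # slight slope to fix orientation
        r = _rot([0, 0, 1], az) @ _rot([0, 1, 0], ay) @ _rot([1, 0, 0], ax)
        n0 = fit_endplate_plane(pts).normal
        n1 = fit_endplate_plane(pts @ r.T).normal
        # normals match up to the cranial-orientation sign convention
        assert min(np.linalg.norm(n1 - r @ n0),
                   np.linalg.norm(n1 + r @ n0)) < 1e-6


class TestCentreOfVolume:
    def test_known_voxel_configurations(self):
        aff = np.eye(4)
        m = np.zeros((5, 5, 5), bool)
        m[1, 2, 3] = True
        assert np.allclose(centre_of_volume(m, aff), [1, 2, 3])
        m[3, 2, 3] = True   # voxels at x=1 and x=3 -> mean x=2
        assert np.allclose(centre_of_volume(m, aff), [2, 2, 3])

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            centre_of_volume(np.zeros((3, 3, 3), bool), np.eye(4))

    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50))
    def test_affine_translation_consistency(self, tx, ty, tz):
        rng = np.random.default_rng(5)
        m = rng.random((8, 8, 8)) > 0.6
        m[0, 0, 0] = True
        aff = np.eye(4)
        c0 = centre_of_volume(m, aff)
        aff2 = aff.copy()
        aff2[:3, 3] += [tx, ty, tz]
        assert np.allclose(centre_of_volume(m, aff2),
                           c0 + [tx, ty, tz], atol=1e-9)

    def test_matches_exhaustive_scan(self, tiny_volume):
        for name in ("A", "B"):
            got = centre_of_volume(tiny_volume.mask(name), tiny_volume.affine)
            want = brute_force_cov(tiny_volume.mask(name), tiny_volume.affine)
            assert np.allclose(got, want, atol=1e-9)


def _cylinder_volume(radius=8.0, height=30.0, tilt_deg=0.0, vox=1.0):
    """Axis-tilted solid cylinder on a vox-mm grid."""
    n = 48
    aff = np.eye(4) * vox
    aff[3, 3] = 1.0
    aff[:3, 3] = -n * vox / 2
    idx = np.indices((n, n, n)).reshape(3, -1).T
    pts = idx * vox + aff[:3, 3]
    axis = _rot([0, 1, 0], tilt_deg) @ np.array([0, 0, 1.0])
    w = pts @ axis
    radial = pts - np.outer(w, axis)
    inside = (np.linalg.norm(radial, axis=1) <= radius) & (np.abs(w) <= height / 2)
    data = np.zeros((n, n, n), dtype=np.int16)
    data[tuple(idx[inside].T)] = 1
    return LabelledVolume(data=data, label_map={"CYL": 1}, affine=aff), axis


class TestResampleTrueAxial:
    def test_midheight_section_area_matches_circle(self):
        vol, axis = _cylinder_volume()
        sec = resample_true_axial(vol, Plane3D([0, 0, 0], axis), ["CYL"])
        area = len(sec.coords["CYL"]) * 1.0  # 1 mm^2 per voxel in the slab
        assert area == pytest.approx(np.pi * 8 ** 2, rel=0.10)

    def test_tilted_cylinder_gives_circular_not_elliptical_mask(self):
        vol, axis = _cylinder_volume(tilt_deg=20.0)
        sec = resample_true_axial(vol, Plane3D([0, 0, 0], axis), ["CYL"])
        q = sec.coords["CYL"] - sec.coords["CYL"].mean(axis=0)
        cov = q.T @ q / len(q)
        radii = np.sqrt(np.linalg.eigvalsh(cov))
        # equal in-plane principal radii = circular cross-section
        assert radii[1] / radii[0] == pytest.approx(1.0, abs=0.08)
        assert 2.0 * radii[1] == pytest.approx(8.0, rel=0.10)  # r = 2 sigma

    def test_plane_outside_volume_raises(self):
        vol, axis = _cylinder_volume()
        with pytest.raises(ValueError, match="outside"):
            resample_true_axial(vol, Plane3D([0, 0, 500.0], [0, 0, 1]), ["CYL"])

    def test_label_missing_from_slab_raises_naming_it(self, tiny_volume):
        # plane through structure A only; B does not intersect it
        plane = Plane3D([-5.0, 0.0, 0.0], [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="'B'"):
            resample_true_axial(tiny_volume, plane, ["A", "B"])
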