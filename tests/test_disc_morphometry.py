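"""Disc/nucleus CoV distance and mid-coronal EC/XC asymmetry."""

import numpy as np
import pytest

from spinemorph import (LabelledVolume, compose_ivd, cov_distance,
                        disc_report, midcoronal_asymmetry)

from conftest import brute_force_cov, brute_force_extremes


def _ellipsoid_mask(shape, centre, radii):
    idx = np.indices(shape).reshape(3, -1).T
    q = (idx - np.asarray(centre)) / np.asarray(radii)
    m = np.zeros(shape, bool)
    m[tuple(idx[(q ** 2).sum(axis=1) <= 1].T)] = True
    return m


class TestComposeIVD:
    def test_union_of_disjoint_masks(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[:2] = True      # 128 voxels
        b[4:5] = True     # 64 voxels
        assert compose_ivd(a, b).sum() == 192

    def test_empty_annulus_gives_nucleus_back(self):
        a = np.zeros((4, 4, 4), bool)
        a[1, 1, 1] = True
        out = compose_ivd(a, np.zeros_like(a))
        assert np.array_equal(out, a)

    def test_overlap_is_a_segmentation_error(self):
        a = np.zeros((4, 4, 4), bool)
        a[1] = True
        with pytest.raises(ValueError, match="overlap"):
            compose_ivd(a, a)

    def test_phantom_disc_volume_close_to_analytic(self, nsp_phantom):
        vol, truth = nsp_phantom
        ap = truth.apical_disc
        ivd = compose_ivd(vol.mask(f"NP_{ap}"), vol.mask(f"AF_{ap}"))
        p = truth.params
        analytic = np.pi * p.body_radius_mm * p.body_ap_radius_mm \
            * p.disc_height_mm
        assert ivd.sum() == pytest.approx(analytic, rel=0.05)


class TestCovDistance:
    def test_three_four_five_triangle(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[1, 2, 3] = True
        b[4, 6, 3] = True
        assert cov_distance(a, b, np.eye(4)) == pytest.approx(5.0)

    def test_concentric_masks_give_zero(self):
        m = _ellipsoid_mask((21, 21, 21), (10, 10, 10), (8, 6, 4))
        inner = _ellipsoid_mask((21, 21, 21), (10, 10, 10), (4, 3, 2))
        assert cov_distance(inner, m, np.eye(4)) == pytest.approx(0.0, abs=1e-9)

    def test_empty_mask_raises(self):
        m = np.zeros((4, 4, 4), bool)
        full = ~m
        with pytest.raises(ValueError, match="empty"):
            cov_distance(m, full, np.eye(4))


class TestMidcoronalAsymmetry:
    def test_symmetric_ellipsoid_has_no_asymmetry(self):
        m = _ellipsoid_mask((31, 21, 15), (15, 10, 7), (12, 7, 5))
        ec, xc, asym, _ = midcoronal_asymmetry(m, np.eye(4), "left")
        assert abs(asym) <= 1.0   # within one voxel

    def test_halved_shape_matches_exhaustive_slab_scan(self):
        m = _ellipsoid_mask((31, 21, 15), (15, 10, 7), (12, 7, 5))
        m[:9] = False    # cut away the concave-side mass beyond a plane
        ec, xc, asym, extras = midcoronal_asymmetry(m, np.eye(4), "left")
        cov = brute_force_cov(m, np.eye(4))
        lo, hi = brute_force_extremes(m, np.eye(4), cov)
        assert np.allclose(extras["concave_point"], lo, atol=1e-9)
        assert np.allclose(extras["convex_point"], hi, atol=1e-9)
        assert ec == pytest.approx(np.linalg.norm(lo - cov), abs=1e-9)
        assert xc == pytest.approx(np.linalg.norm(hi - cov), abs=1e-9)

    def test_mirror_with_convexity_swap_negates_asymmetry_exactly(self):
        m = _ellipsoid_mask((31, 21, 15), (15, 10, 7), (12, 7, 5))
        m[:11] = False
        aff = np.eye(4)
        _, _, asym, _ = midcoronal_asymmetry(m, aff, "left")
        mirror = aff.copy()
        mirror[0, 0] = -1.0           # x -> -x about the sagittal midplane
        _, _, asym_m, _ = midcoronal_asymmetry(m, mirror, "right")
        assert asym_m == pytest.approx(asym, abs=1e-12)
        _, _, asym_swap, _ = midcoronal_asymmetry(m, mirror, "left")
        assert asym_swap == pytest.approx(-asym, abs=1e-12)

    def test_translation_invariance_to_nanometres(self):
        m = _ellipsoid_mask((31, 21, 15), (15, 10, 7), (12, 7, 5))
        m[:11] = False
        aff = np.eye(4)
        ec0, xc0, asym0, _ = midcoronal_asymmetry(m, aff, "left")
        aff2 = aff.copy()
        aff2[:3, 3] += [13.25, -7.5, 101.0]
        ec1, xc1, asym1, _ = midcoronal_asymmetry(m, aff2, "left")
        assert ec1 == pytest.approx(ec0, abs=1e-9)
        assert asym1 == pytest.approx(asym0, abs=1e-9)

    def test_missing_convexity_side_rejected(self):
        m = np.ones((3, 3, 3), bool)
        with pytest.raises(ValueError, match="convexity"):
            midcoronal_asymmetry(m, np.eye(4), "up")


class TestDiscReport:
    def test_identical_positions_have_zero_deltas(self, coarse_phantom):
        vol, truth = coarse_phantom
        df = disc_report((vol, vol), truth.np_disc_names, truth.apical_disc,
                         truth.convexity)
        assert np.allclose(df["delta_d_mm"], 0.0)
        assert np.allclose(df["delta_asymmetry_mm"], 0.0)
        assert set(df["structure"]) == {"IVD", "NP"}
        assert set(df["position"]) == {"NSP", "ESP"}

    def test_wedged_apical_disc_normalises_under_extension(self, phantom_pair):
        (vn, tn), (ve, _) = phantom_pair
        df = disc_report((vn, ve), tn.np_disc_names, tn.apical_disc,
                         tn.convexity)
        ivd = df[(df.structure == "IVD") & df.apical]
        nsp = float(ivd[ivd.position == "NSP"].asymmetry_mm.iloc[0])
        esp = float(ivd[ivd.position == "ESP"].asymmetry_mm.iloc[0])
        assert nsp > 0
        assert esp < nsp

    def test_disc_missing_in_one_position_named_in_error(self, coarse_phantom):
        vol, truth = coarse_phantom
        broken_map = {k: v for k, v in vol.label_map.items()
                      if k != f"NP_{truth.apical_disc}"}
        broken = LabelledVolume(data=vol.data, label_map=broken_map,
                                affine=vol.affine)
        with pytest.raises(ValueError, match=truth.apical_disc):
            disc_report((vol, broken), truth.np_disc_names, truth.apical_disc,
                        truth.convexity)
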