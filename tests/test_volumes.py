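"""Structure-mask algebra: expansion, subtraction, cropping, volumes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import hypofx as hx
from hypofx.volumes import (
    crop_from_surface,
    exterior_distance,
    expand_mask,
    mask_volume,
    read_dose_nifti,
    read_mask_nifti,
    subtract_mask,
    write_dose_nifti,
    write_mask_nifti,
)

from conftest import make_geometry, make_mask


def brute_force_expand(mask, margin_mm):
    """O(N*M) reference: voxel centers within margin of any mask voxel."""
    geom = mask.geometry
    sp = np.array(geom.spacing)
    pts = np.argwhere(mask.occupancy) * sp
    out = np.zeros(geom.shape, dtype=bool)
    for idx in np.ndindex(geom.shape):
        p = np.array(idx) * sp
        if pts.size and np.min(np.linalg.norm(pts - p, axis=1)) <= margin_mm + 1e-9:
            out[idx] = True
    return out


def brute_force_exterior_distance(body):
    geom = body.geometry
    sp = np.array(geom.spacing)
    outside = np.argwhere(~body.occupancy) * sp
    dist = np.zeros(geom.shape)
    for idx in np.ndindex(geom.shape):
        if body.occupancy[idx]:
            p = np.array(idx) * sp
            dist[idx] = np.min(np.linalg.norm(outside - p, axis=1)) if outside.size else np.inf
    return dist


class TestExpandMask:
    def test_single_voxel_2mm_margin_is_33_voxels(self):
        # integer offsets with dx^2+dy^2+dz^2 <= 4 on a 1 mm grid: 33 centers
        geom = make_geometry((5, 5, 5))
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[2, 2, 2] = True
        grown = expand_mask(make_mask(occ, geom), 2.0)
        assert grown.voxel_count == 33
        assert (grown.occupancy == brute_force_expand(make_mask(occ, geom), 2.0)).all()

    def test_zero_margin_is_identity(self):
        occ = np.random.default_rng(0).random((4, 4, 4)) > 0.5
        m = make_mask(occ)
        assert (expand_mask(m, 0.0).occupancy == occ).all()

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            expand_mask(make_mask(np.ones((2, 2, 2), bool)), -1.0)

    def test_clipped_at_bounds(self):
        occ = np.zeros((3, 3, 3), dtype=bool)
        occ[0, 0, 0] = True
        grown = expand_mask(make_mask(occ), 10.0)
        assert grown.occupancy.all()  # fills the grid, no error

    def test_anisotropic_spacing_uses_physical_distance(self):
        # 2 mm along x but 1 mm along y: a 1.5 mm margin reaches one y
        # neighbour but no x neighbour
        geom = make_geometry((3, 3, 1), spacing=(2.0, 1.0, 1.0))
        occ = np.zeros((3, 3, 1), dtype=bool)
        occ[1, 1, 0] = True
        grown = expand_mask(make_mask(occ, geom), 1.5)
        assert grown.occupancy[1, 0, 0] and grown.occupancy[1, 2, 0]
        assert not grown.occupancy[0, 1, 0] and not grown.occupancy[2, 1, 0]

    @given(
        occ=hnp.arrays(bool, (5, 5, 5)),
        margin=st.floats(0, 4),
    )
    @settings(max_examples=30)
    def test_matches_brute_force_and_is_extensive(self, occ, margin):
        m = make_mask(occ)
        grown = expand_mask(m, margin)
        assert (grown.occupancy & ~brute_force_expand(m, margin)).sum() == 0
        assert (brute_force_expand(m, margin) & ~grown.occupancy).sum() == 0
        assert (m.occupancy & ~grown.occupancy).sum() == 0  # m is contained

    def test_monotone_in_mask(self):
        rng = np.random.default_rng(1)
        small = rng.random((6, 6, 6)) > 0.8
        big = small | (rng.random((6, 6, 6)) > 0.8)
        g_small = expand_mask(make_mask(small), 2.0)
        g_big = expand_mask(make_mask(big), 2.0)
        assert (g_small.occupancy & ~g_big.occupancy).sum() == 0

    def test_shell_distances_bounded_by_margin(self):
        geom = make_geometry((9, 9, 9))
        occ = np.zeros((9, 9, 9), dtype=bool)
        occ[4, 4, 4] = True
        m = make_mask(occ, geom)
        margin = 3.0
        shell = subtract_mask(expand_mask(m, margin), m)
        pts = np.argwhere(shell.occupancy).astype(float)
        dists = np.linalg.norm(pts - 4.0, axis=1)
        assert dists.min() > 0 and dists.max() <= margin + 1e-9


class TestSubtractMask:
    def test_self_subtraction_empty(self):
        m = make_mask(np.ones((3, 3, 3), bool))
        assert subtract_mask(m, m).voxel_count == 0

    def test_contained_subtraction_volume_identity(self):
        body = np.ones((4, 4, 4), dtype=bool)
        inner = np.zeros((4, 4, 4), dtype=bool)
        inner[1:3, 1:3, 1:3] = True
        a, b = make_mask(body, name="body"), make_mask(inner, name="ctv")
        assert mask_volume(subtract_mask(a, b)) == pytest.approx(
            mask_volume(a) - mask_volume(b)
        )

    def test_disjoint_masks_unchanged(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[3] = True, True
        assert (subtract_mask(make_mask(a), make_mask(b)).occupancy == a).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="congruent"):
            subtract_mask(make_mask(np.ones((3, 3, 3), bool)), make_mask(np.ones((4, 4, 4), bool)))


class TestCropFromSurface:
    def _body(self):
        occ = np.zeros((9, 9, 9), dtype=bool)
        occ[1:8, 1:8, 1:8] = True
        return make_mask(occ, make_geometry((9, 9, 9)), name="body")

    def test_depth_zero_is_intersection(self):
        body = self._body()
        m = make_mask(np.ones((9, 9, 9), bool))
        out = crop_from_surface(m, body, 0.0)
        assert (out.occupancy == body.occupancy).all()

    def test_surface_shell_removed_matches_brute_force(self):
        body = self._body()
        m = make_mask(body.occupancy.copy())
        depth = 2.0
        out = crop_from_surface(m, body, depth)
        ref = body.occupancy & (brute_force_exterior_distance(body) >= depth - 1e-9)
        assert (out.occupancy == ref).all()
        assert out.voxel_count < m.voxel_count  # a shell actually went away

    def test_deep_interior_mask_unchanged(self):
        body = self._body()
        occ = np.zeros((9, 9, 9), dtype=bool)
        occ[4, 4, 4] = True
        out = crop_from_surface(make_mask(occ), body, 3.0)
        assert (out.occupancy == occ).all()

    def test_depth_negative_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            crop_from_surface(self._body(), self._body(), -0.5)


class TestMaskVolume:
    def test_empty_mask_zero(self):
        assert mask_volume(make_mask(np.zeros((3, 3, 3), bool))) == 0.0

    def test_unit_conversion(self):
        occ = np.ones((10, 10, 10), dtype=bool)  # 1000 voxels of 1 mm^3
        assert mask_volume(make_mask(occ)) == pytest.approx(1.0)

    def test_sphere_volume_close_to_analytic(self):
        geom = make_geometry((40, 40, 40), spacing=(2.0, 2.0, 2.0))
        ax = geom.coordinate_axes()
        r = 30.0
        c = ax[0][len(ax[0]) // 2]
        occ = (
            (ax[0][:, None, None] - c) ** 2
            + (ax[1][None, :, None] - c) ** 2
            + (ax[2][None, None, :] - c) ** 2
        ) <= r**2
        vol = mask_volume(make_mask(occ, geom))
        analytic = 4.0 / 3.0 * np.pi * r**3 / 1000.0  # ~113.1 cc
        # discretization error bounded by about one voxel layer on the surface
        shell = 4 * np.pi * r**2 * 2.0 / 1000.0
        assert abs(vol - analytic) < shell

    def test_additive_over_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[:2], b[2:] = True, True
        ma, mb = make_mask(a), make_mask(b)
        both = make_mask(a | b)
        assert mask_volume(both) == pytest.approx(mask_volume(ma) + mask_volume(mb))


class TestNiftiIO:
    def test_dose_round_trip(self, tmp_path):
        geom = make_geometry((5, 6, 7), spacing=(2.0, 2.5, 3.0))
        values = np.random.default_rng(0).random((5, 6, 7)) * 30
        grid = hx.DoseGrid(values, geom)
        path = tmp_path / "dose.nii.gz"
        write_dose_nifti(grid, path)
        back = read_dose_nifti(path)
        assert back.geometry == geom
        np.testing.assert_allclose(back.values, values, rtol=1e-6)

    def test_mask_round_trip(self, tmp_path):
        geom = make_geometry((5, 6, 7), spacing=(2.0, 2.5, 3.0))
        occ = np.random.default_rng(1).random((5, 6, 7)) > 0.5
        path = tmp_path / "mask.nii.gz"
        write_mask_nifti(hx.StructureMask("liver", occ, geom), path)
        back = read_mask_nifti(path, "liver")
        assert back.geometry == geom
        assert (back.occupancy == occ).all()


def test_structure_set_rejects_incongruent_and_duplicate():
    geom = make_geometry((3, 3, 3))
    ss = hx.StructureSet(geom)
    ss.add(hx.StructureMask("a", np.ones((3, 3, 3), bool), geom))
    with pytest.raises(ValueError, match="duplicate"):
        ss.add(hx.StructureMask("a", np.ones((3, 3, 3), bool), geom))
    other = make_geometry((3, 3, 3), spacing=(2.0, 1.0, 1.0))
    with pytest.raises(ValueError, match="geometry"):
        ss.add(hx.StructureMask("b", np.ones((3, 3, 3), bool), other))
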