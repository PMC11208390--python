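"""Cropping layouts, primary allocation, mosaicking and overlap regions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import patchdose as pdx
from patchdose.kernel import convolve_tia
from patchdose.layouts import _coverage


def tia_grid(values, voxel=9.59):
    return pdx.VoxelGrid(np.asarray(values, dtype=float), (voxel,) * 3, role="TIA")


def linear_patch_doses(ps, kernel):
    """Deterministic linear dose engine: convolve each source patch."""
    return [convolve_tia(src, kernel, method="direct") for src in ps.source_patches]


class TestMinOverlap:
    @pytest.mark.parametrize("r,v,expected", [
        (11.3, 9.59, 4),   # ceil(2*11.3/9.59) = 3 -> even, ties upward
        (9.59, 9.59, 2),   # exactly even
        (5.0, 10.0, 2),    # OV_min = 1 forced up to 2
    ])
    def test_even_rounding(self, r, v, expected):
        assert pdx.min_overlap_voxels(r, v) == expected

    def test_never_odd_never_below_min(self):
        for r in np.linspace(0.5, 40, 80):
            ov = pdx.min_overlap_voxels(r, 9.59)
            assert ov % 2 == 0
            assert ov >= int(np.ceil(2 * r / 9.59)) - 1

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            pdx.min_overlap_voxels(0.0, 9.59)


class TestLayoutSpec:
    def test_geometry_edges(self):
        assert pdx.LayoutSpec("CL1", 32).geometry_edge == 32
        assert pdx.LayoutSpec("CL2", 32, 4).geometry_edge == 40
        assert pdx.LayoutSpec("CL3", 24, 4).geometry_edge == 32

    def test_validation(self):
        with pytest.raises(ValueError):
            pdx.LayoutSpec("CL1", 32, 4)
        with pytest.raises(ValueError):
            pdx.LayoutSpec("CL2", 32, 3)  # odd overlap
        with pytest.raises(ValueError):
            pdx.LayoutSpec("CL3", 32, 0)
        pdx.LayoutSpec("CL3", 32, 4).validate_overlap(11.3, 9.59)
        with pytest.raises(ValueError):
            pdx.LayoutSpec("CL3", 32, 2).validate_overlap(11.3, 9.59)


class TestCrop:
    @pytest.fixture()
    def volumes(self, rng):
        v = rng.random((64, 64, 42))
        return tia_grid(v), tia_grid(np.zeros((64, 64, 42)))

    def test_cl1_eight_patches_at_expected_origins(self, volumes):
        tia, ct = volumes
        ps = pdx.crop(tia, ct, pdx.LayoutSpec("CL1", 32))
        assert ps.n_patches == 8
        assert set(ps.origins) == {(i, j, k) for i in (0, 32)
                                   for j in (0, 32) for k in (0, 32)}
        assert all(p.shape == (32, 32, 32) for p in ps.source_patches)

    def test_cl3_geometry_40_and_band_overlap(self, volumes):
        tia, ct = volumes
        ps = pdx.crop(tia, ct, pdx.LayoutSpec("CL3", 32, 4))
        assert ps.n_patches == 8
        assert all(p.shape == (40, 40, 40) for p in ps.geometry_patches)
        # adjacent geometry patches share an 8-voxel band
        cov = _coverage(ps)
        assert cov[35, 10, 10] == 2 and cov[27, 10, 10] == 1
        assert cov.max() == 8

    def test_cl3_stride_24_gives_18_patches(self, volumes):
        tia, ct = volumes
        ps = pdx.crop(tia, ct, pdx.LayoutSpec("CL3", 24, 4))
        assert ps.n_patches == 18
        assert ps.layout.geometry_edge == 32

    def test_tia_partition_exact_for_cl1_and_cl3(self, volumes):
        tia, ct = volumes
        for spec in (pdx.LayoutSpec("CL1", 32), pdx.LayoutSpec("CL3", 32, 4)):
            ps = pdx.crop(tia, ct, spec)
            assert sum(ps.tia_sums) == pytest.approx(tia.values.sum(), rel=1e-12)

    def test_cl2_source_patches_overcount_band_activity(self, volumes):
        tia, ct = volumes
        ps = pdx.crop(tia, ct, pdx.LayoutSpec("CL2", 32, 4))
        assert sum(ps.tia_sums) > tia.values.sum()

    def test_misaligned_rejected(self, volumes):
        tia, _ = volumes
        other = pdx.VoxelGrid(np.zeros((64, 64, 42)), (1.0,) * 3)
        with pytest.raises(ValueError):
            pdx.crop(tia, other, pdx.LayoutSpec("CL1", 32))


class TestAllocatePrimaries:
    @pytest.mark.parametrize("total,count,first,allsame", [
        (500_000_000, 8, 62_500_000, True),
        (500_000_000, 18, 27_777_778, False),
        (7, 2, 4, False),
    ])
    def test_worked_examples(self, total, count, first, allsame):
        alloc = pdx.allocate_primaries(total, count)
        assert alloc[0] == first
        assert sum(alloc) == total
        assert (len(set(alloc)) == 1) == allsame

    @given(total=st.integers(1, 10**9), count=st.integers(1, 64))
    def test_sum_preserved_and_balanced(self, total, count):
        alloc = pdx.allocate_primaries(total, count)
        assert sum(alloc) == total
        assert max(alloc) - min(alloc) <= 1


class TestScalePatch:
    def test_zero_tia_zero_dose(self):
        d = pdx.VoxelGrid(np.ones((4, 4, 4)), (1,) * 3, role="dose_per_primary")
        assert np.all(pdx.scale_patch(d, 0.0, 100).values == 0)

    def test_linear_in_patch_tia(self):
        d = pdx.VoxelGrid(np.ones((4, 4, 4)), (1,) * 3, role="dose_per_primary")
        a = pdx.scale_patch(d, 2.0, 50)
        b = pdx.scale_patch(d, 1.0, 50)
        np.testing.assert_allclose(a.values, 2 * b.values)


class TestMosaic:
    def test_cl1_roundtrip_identity_on_sources(self, rng):
        # mosaicking the CL1 source patches themselves reproduces the volume
        tia = tia_grid(rng.random((64, 64, 42)))
        ps = pdx.crop(tia, tia.with_values(np.zeros(tia.shape)), pdx.LayoutSpec("CL1", 32))
        out = pdx.mosaic(ps.source_patches, ps)
        np.testing.assert_array_equal(out.values, tia.values)
        assert out.aligned_with(tia)

    def test_cl2_constant_patches_give_constant(self, rng):
        tia = tia_grid(rng.random((16, 16, 16)))
        ps = pdx.crop(tia, tia.with_values(np.zeros(tia.shape)), pdx.LayoutSpec("CL2", 8, 2))
        const = [np.full((12, 12, 12), 3.0)] * ps.n_patches
        out = pdx.mosaic(const, ps)
        np.testing.assert_allclose(out.values, 3.0)

    def test_cl3_single_nonzero_patch_places_values(self, rng):
        tia = tia_grid(rng.random((16, 16, 16)))
        ps = pdx.crop(tia, tia.with_values(np.zeros(tia.shape)), pdx.LayoutSpec("CL3", 8, 2))
        doses = [np.zeros((12, 12, 12)) for _ in range(ps.n_patches)]
        doses[0][5, 5, 5] = 7.0  # interior of the first patch
        out = pdx.mosaic(doses, ps)
        o = ps.geometry_origin_index(0)  # canvas coords; crop_back removes low pads
        idx = tuple(o[a] + 5 - ps.padding.low[a] for a in range(3))
        assert out.values[idx] == 7.0
        assert out.values.sum() == 7.0

    def test_wrong_patch_count_rejected(self, rng):
        tia = tia_grid(rng.random((16, 16, 16)))
        ps = pdx.crop(tia, tia.with_values(np.zeros(tia.shape)), pdx.LayoutSpec("CL1", 8))
        with pytest.raises(ValueError):
            pdx.mosaic([np.zeros((8, 8, 8))], ps)


class TestLinearEngineEquivalence:
    """The layout mechanisms, made deterministic with a compact linear
    dose operator (kernel half-width <= OV)."""

    @pytest.fixture()
    def tia(self, rng):
        return tia_grid(rng.random((20, 18, 14)))

    @pytest.mark.parametrize("shape", ["tent", "uniform"])
    def test_cl3_sum_mosaic_equals_whole_volume(self, tia, shape):
        kernel = pdx.make_toy_kernel(4, 9.59, shape)
        ref = convolve_tia(tia, kernel, method="direct")
        ps = pdx.crop(tia, tia.with_values(np.zeros(tia.shape)), pdx.LayoutSpec("CL3", 8, 4))
        out = pdx.mosaic(linear_patch_doses(ps, kernel), ps)
        nz = ref.values > 0
        assert np.all(np.abs(out.values[nz] - ref.values[nz]) / ref.values[nz] <= 1e-12)
        assert np.all(out.values[~nz] == 0)

    def test_cl1_under_doses_band_uniform_source(self):
        tia = tia_grid(np.ones((24, 24, 24)))
        kernel = pdx.make_toy_kernel(2, 9.59, "tent")
        ref = convolve_tia(tia, kernel, method="direct")
        ps = pdx.crop(tia, tia.with_values(np.zeros(tia.shape)), pdx.LayoutSpec("CL1", 8))
        out = pdx.mosaic(linear_patch_doses(ps, kernel), ps)
        band = pdx.overlap_region_mask(pdx.LayoutSpec("CL2", 8, 2), tia.shape)
        assert np.all(out.values[band] < ref.values[band])
        assert np.all(out.values <= ref.values + 1e-15)

    def test_cl2_under_doses_band_edges_uniform_source(self):
        tia = tia_grid(np.ones((24, 24, 24)))
        kernel = pdx.make_toy_kernel(2, 9.59, "tent")
        ref = convolve_tia(tia, kernel, method="direct")
        ps = pdx.crop(tia, tia.with_values(np.zeros(tia.shape)), pdx.LayoutSpec("CL2", 8, 2))
        out = pdx.mosaic(linear_patch_doses(ps, kernel), ps)
        # outermost band layer (distance OV from the patch boundary plane)
        edge = np.zeros(tia.shape, dtype=bool)
        for b in (8, 16):
            edge[b - 2, 2:-2, 2:-2] = True
            edge[b + 1, 2:-2, 2:-2] = True
        assert np.all(out.values[edge] < ref.values[edge])
        assert np.all(out.values <= ref.values + 1e-15)


class TestOverlapRegionMask:
    def test_band_count_matches_brute_force(self):
        mask = pdx.overlap_region_mask(pdx.LayoutSpec("CL2", 32, 4), (64, 64, 64))
        # brute force: per-axis band indices 28..35
        band1d = np.zeros(64, dtype=bool)
        band1d[28:36] = True
        brute = band1d[:, None, None] | band1d[None, :, None] | band1d[None, None, :]
        assert mask.sum() == 64**3 - 56**3 == 86_528
        np.testing.assert_array_equal(mask, brute)

    def test_single_patch_mask_empty(self):
        mask = pdx.overlap_region_mask(pdx.LayoutSpec("CL2", 64, 4), (64, 64, 42))
        assert not mask.any()

    def test_cl1_requires_reference_overlap(self):
        with pytest.raises(ValueError):
            pdx.overlap_region_mask(pdx.LayoutSpec("CL1", 32), (64, 64, 42))
        m = pdx.overlap_region_mask(pdx.LayoutSpec("CL1", 32), (64, 64, 42),
                                    reference_overlap=4)
        assert m.any()
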