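"""LC contrast extraction: geometry, sampling rules, recovery, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcmri import lc_contrast, synthio
from lcmri.volume import Volume


def make_vol(data, vs=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data, dtype=float), vs)


class TestUpsample:
    def test_factor3_gives_033mm_voxels(self):
        vol = make_vol(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0))
        up = lc_contrast.upsample_volume(vol, 3)
        assert up.voxel_size == pytest.approx((1 / 3, 1 / 3, 1 / 3))
        assert up.shape == (12, 12, 12)

    def test_factor1_identity(self):
        vol = make_vol(np.random.default_rng(0).normal(size=(3, 3, 3)))
        up = lc_contrast.upsample_volume(vol, 1)
        assert np.array_equal(up.data, vol.data)
        assert up.voxel_size == vol.voxel_size

    def test_constant_volume_stays_constant(self):
        vol = make_vol(np.full((2, 2, 2), 7.0))
        up = lc_contrast.upsample_volume(vol, 3)
        assert up.shape == (6, 6, 6)
        assert np.all(up.data == 7.0)

    def test_nearest_preserves_values(self):
        vol = make_vol(np.arange(8).reshape(2, 2, 2))
        up = lc_contrast.upsample_volume(vol, 2)
        assert set(np.unique(up.data)) == set(range(8))

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            lc_contrast.upsample_volume(make_vol(np.zeros((2, 2, 2))), 1.5)

    def test_linear_mode_runs(self):
        vol = make_vol(np.random.default_rng(1).normal(size=(4, 4, 4)))
        up = lc_contrast.upsample_volume(vol, 2, method="linear")
        assert up.shape == (8, 8, 8)


class TestIntersect:
    def test_identical_masks(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        assert np.array_equal(lc_contrast.intersect_masks(m, m), m)

    def test_disjoint_masks_error_names_sizes(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0, 0, 0] = True
        b[2, 2, 2] = True
        with pytest.raises(ValueError, match="sizes 1 and 1"):
            lc_contrast.intersect_masks(a, b)

    def test_hand_intersection(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        for v in [(1, 1, 1), (1, 2, 1), (2, 1, 1)]:
            a[v] = True
        for v in [(1, 2, 1), (9, 9, 9)]:
            b[v] = True
        inter = lc_contrast.intersect_masks(a, b)
        assert np.argwhere(inter).tolist() == [[1, 2, 1]]


class TestSubdivision:
    @pytest.mark.parametrize(
        "n,expected",
        [(8, (2, 4, 2)), (12, (3, 6, 3)), (5, (1, 3, 1)), (4, (1, 2, 1)), (7, (1, 5, 1))],
    )
    def test_floor_rule_counts(self, n, expected):
        mask = np.zeros((3, 3, n + 2), bool)
        mask[1, 1, 1 : n + 1] = True
        region = lc_contrast.subdivide_rostrocaudal(mask)
        counts = tuple(
            len(region.subpart_slices(p)) for p in ("caudal", "medial", "rostral")
        )
        assert counts == expected
        assert sum(counts) == region.n_slices == n

    def test_caudal_is_inferior_rostral_superior(self):
        mask = np.zeros((3, 3, 10), bool)
        mask[1, 1, 1:9] = True
        region = lc_contrast.subdivide_rostrocaudal(mask)
        assert max(region.subpart_slices("caudal")) < min(region.subpart_slices("medial"))
        assert max(region.subpart_slices("medial")) < min(region.subpart_slices("rostral"))

    def test_too_few_slices_rejected(self):
        mask = np.zeros((3, 3, 5), bool)
        mask[1, 1, 1:4] = True
        with pytest.raises(ValueError, match="at least 4"):
            lc_contrast.subdivide_rostrocaudal(mask)

    def test_non_contiguous_slices_rejected(self):
        mask = np.zeros((3, 3, 8), bool)
        mask[1, 1, [1, 2, 4, 5]] = True
        with pytest.raises(ValueError, match="contiguous"):
            lc_contrast.subdivide_rostrocaudal(mask)


class TestPeakCross:
    def test_single_hot_voxel_in_zero_background(self):
        data = np.zeros((9, 9, 3))
        data[4, 4, 1] = 10.0
        mask = np.zeros((9, 9, 3), bool)
        mask[3:6, 3:6, 1] = True
        peak, mean = lc_contrast.peak_cross_mean(make_vol(data), mask, 1)
        assert peak == (4, 4)
        assert mean == pytest.approx(10.0 / 5)

    def test_constant_slice_returns_value(self):
        data = np.full((9, 9, 3), 3.5)
        mask = np.zeros((9, 9, 3), bool)
        mask[3:6, 3:6, 1] = True
        _, mean = lc_contrast.peak_cross_mean(make_vol(data), mask, 1)
        assert mean == pytest.approx(3.5)

    def test_two_equal_maxima_take_smaller_xy(self):
        data = np.zeros((9, 9, 3))
        data[2, 2, 1] = 5.0
        data[6, 6, 1] = 5.0
        mask = np.ones((9, 9, 3), bool)
        peak, _ = lc_contrast.peak_cross_mean(make_vol(data), mask, 1)
        assert peak == (2, 2)

    def test_cross_out_of_bounds_rejected(self):
        data = np.zeros((5, 5, 3))
        data[0, 2, 1] = 9.0
        mask = np.ones((5, 5, 3), bool)
        with pytest.raises(ValueError, match="bounds"):
            lc_contrast.peak_cross_mean(make_vol(data), mask, 1)

    def test_through_plane_mode_uses_axial_neighbors(self):
        data = np.zeros((9, 9, 3))
        data[4, 4, 1] = 10.0
        data[4, 4, 0] = 2.0
        data[4, 4, 2] = 3.0
        mask = np.zeros((9, 9, 3), bool)
        mask[4, 4, 1] = True
        _, mean = lc_contrast.peak_cross_mean(
            make_vol(data), mask, 1, mode="through-plane"
        )
        assert mean == pytest.approx((10 + 2 + 3) / 5)


class TestReferenceMean:
    def test_constant_region(self):
        vol = make_vol(np.full((31, 31, 3), 4.0))
        spec = lc_contrast.ReferenceSpec(centers={1: (15, 15)})
        mean, center = lc_contrast.reference_mean(vol, 1, spec)
        assert mean == pytest.approx(4.0)
        assert center == (15, 15)

    def test_checkerboard_mean(self):
        # 15x15 alternating 0/1 starting with 1 -> 113 ones of 225 voxels
        data = np.zeros((15, 15, 1))
        data[:, :, 0] = (np.indices((15, 15)).sum(axis=0) + 1) % 2
        spec = lc_contrast.ReferenceSpec(centers={0: (7, 7)})
        mean, _ = lc_contrast.reference_mean(make_vol(data), 0, spec)
        assert mean == pytest.approx(113 / 225)

    def test_region_spans_495mm_at_upsampled_resolution(self):
        # factor-3 upsampling of a 1 mm grid prints as 0.33 mm voxels, and
        # 15 x 0.33 mm = 4.95 mm per side at that printed precision
        vol = lc_contrast.upsample_volume(
            make_vol(np.zeros((20, 20, 3)), (1.0, 1.0, 1.0)), 3
        )
        edge_printed = round(vol.voxel_size[0], 2)
        assert edge_printed == 0.33
        spec = lc_contrast.ReferenceSpec()
        assert spec.size * edge_printed == pytest.approx(4.95, abs=1e-12)

    def test_out_of_bounds_error_names_slice(self):
        vol = make_vol(np.zeros((10, 10, 3)))
        spec = lc_contrast.ReferenceSpec(centers={2: (1, 1)})
        with pytest.raises(ValueError, match="slice 2"):
            lc_contrast.reference_mean(vol, 2, spec)

    def test_rule_based_placement_is_anterior_to_peak(self):
        vol = make_vol(np.zeros((41, 41, 3)))
        spec = lc_contrast.ReferenceSpec(anterior_offset=10)
        _, center = lc_contrast.reference_mean(vol, 1, spec, peak=(20, 30))
        assert center == (20, 20)


class TestComputeContrast:
    def _flat_region(self, shape=(41, 41, 8)):
        mask = np.zeros(shape, bool)
        mask[18:23, 28:33, 1:7] = True
        return lc_contrast.subdivide_rostrocaudal(mask)

    def test_equal_lc_and_reference_gives_zero(self):
        region = self._flat_region()
        vol = make_vol(np.full((41, 41, 8), 9.0))
        res = lc_contrast.compute_contrast(
            vol, region, lc_contrast.ReferenceSpec(anterior_offset=20)
        )
        for part in ("caudal", "medial", "rostral", "whole"):
            assert res.contrast(part) == pytest.approx(0.0, abs=1e-15)

    def test_fixed_ratio_gives_ratio_minus_one(self):
        region = self._flat_region()
        data = np.full((41, 41, 8), 10.0)
        data[region.mask] = 12.0
        res = lc_contrast.compute_contrast(
            make_vol(data), region, lc_contrast.ReferenceSpec(anterior_offset=20)
        )
        assert res.contrast("whole") == pytest.approx(0.2, abs=1e-12)

    def test_noiseless_phantom_recovery_exact(
        self, noiseless_phantom, left_region, reference_spec
    ):
        vol, _, _ = noiseless_phantom
        res = lc_contrast.compute_contrast(vol, left_region, reference_spec)
        for part in ("caudal", "medial", "rostral", "whole"):
            assert res.contrast(part) == pytest.approx(0.15, abs=1e-12)

    def test_nonpositive_reference_rejected(self):
        region = self._flat_region()
        data = np.zeros((41, 41, 8))
        data[region.mask] = 5.0
        with pytest.raises(ValueError, match="reference"):
            lc_contrast.compute_contrast(
                make_vol(data), region, lc_contrast.ReferenceSpec(anterior_offset=20)
            )


class TestInvariances:
    @given(k=st.floats(min_value=1e-3, max_value=1e4))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, k):
        spec = synthio.PhantomSpec(contrast_ratio=1.2, noise_sd=3.0, seed=21)
        vol, _, _ = synthio.generate_lc_phantom(spec)
        side = synthio.rasterize_tube(
            spec.lc_centerlines[0], spec.shape, spec.voxel_size, spec.lc_radius
        )
        region = lc_contrast.subdivide_rostrocaudal(side)
        ref = lc_contrast.ReferenceSpec(anterior_offset=25)
        base = lc_contrast.compute_contrast(vol, region, ref)
        scaled = lc_contrast.compute_contrast(
            Volume(vol.data * k, vol.voxel_size), region, ref
        )
        for part in ("caudal", "medial", "rostral", "whole"):
            assert scaled.contrast(part) == pytest.approx(
                base.contrast(part), abs=1e-12
            )

    def test_whole_contrast_independent_of_subpart_boundaries(
        self, noiseless_phantom, left_region, reference_spec
    ):
        vol, _, _ = noiseless_phantom
        res = lc_contrast.compute_contrast(vol, left_region, reference_spec)
        # recompute slice-wise and average manually
        vals = [
            s.normalized
            for part in ("caudal", "medial", "rostral")
            for s in res.subparts[part].samples
        ]
        assert res.contrast("whole") == pytest.approx(np.mean(vals), abs=1e-14)

    def test_raising_lc_intensity_raises_every_subpart(
        self, noiseless_phantom, left_region, reference_spec
    ):
        vol, mask, _ = noiseless_phantom
        res = lc_contrast.compute_contrast(vol, left_region, reference_spec)
        boosted = vol.data.copy()
        boosted[mask] += 5.0
        res2 = lc_contrast.compute_contrast(
            Volume(boosted, vol.voxel_size), left_region, reference_spec
        )
        for part in ("caudal", "medial", "rostral", "whole"):
            assert res2.contrast(part) > res.contrast(part)


class TestFullPipeline:
    def test_extract_contrast_with_jittered_raters(self, noiseless_phantom_spec):
        spec = noiseless_phantom_spec
        vol, _, _ = synthio.generate_lc_phantom(spec)
        side = synthio.rasterize_tube(
            spec.lc_centerlines[0], spec.shape, spec.voxel_size, spec.lc_radius
        )
        m1, m2, dice = synthio.perturb_rater_masks(side, 1, seed=13)
        res = lc_contrast.extract_contrast(
            vol,
            m1,
            m2,
            side="left",
            factor=1,
            ref_spec=lc_contrast.ReferenceSpec(anterior_offset=25),
        )
        assert dice < 1.0
        # the intersection stays inside the true tube, so the noiseless
        # contrast is still exact
        assert res.contrast("whole") == pytest.approx(0.15, abs=1e-12)

    def test_upsampled_pipeline_consistent(self, noiseless_phantom_spec):
        spec = noiseless_phantom_spec
        vol, _, _ = synthio.generate_lc_phantom(spec)
        side = synthio.rasterize_tube(
            spec.lc_centerlines[0], spec.shape, spec.voxel_size, spec.lc_radius
        )
        res = lc_contrast.extract_contrast(
            vol,
            side,
            side,
            side="left",
            factor=3,
            ref_spec=lc_contrast.ReferenceSpec(anterior_offset=75),
        )
        assert res.contrast("whole") == pytest.approx(0.15, abs=1e-12)
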