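import itertools

import numpy as np
import pytest

from petrad import imaging
from petrad.imaging import WindowSpec


def brute_force_suv_peak(pet, mask, spacing=(1.0, 1.0, 1.0)):
    """Exhaustive sphere search oracle: loop over every in-mask center."""
    radius = imaging.PEAK_SPHERE_RADIUS_MM
    spacing = np.asarray(spacing)
    best = -np.inf
    centers = np.argwhere(np.asarray(mask).astype(bool))
    coords = np.array(list(np.ndindex(pet.shape)))
    phys = coords * spacing
    flat = np.asarray(pet).ravel()
    for c in centers:
        d2 = ((phys - c * spacing) ** 2).sum(axis=1)
        inside = d2 <= radius ** 2
        best = max(best, flat[inside].mean())
    return best


class TestWindowCt:
    def test_endpoints_and_midpoint(self):
        vol = np.array([[[-30.0, 170.0, 70.0]]])
        out = imaging.window_ct(vol, WindowSpec(70, 200))
        np.testing.assert_allclose(out, [[[0.0, 1.0, 0.5]]])

    def test_extreme_value_clipped(self):
        assert imaging.window_ct(np.array([[[1000.0]]]))[0, 0, 0] == 1.0

    def test_constant_volume_at_center(self):
        out = imaging.window_ct(np.full((3, 3, 3), 70.0))
        assert np.all(out == 0.5)

    def test_idempotent_after_rescaling_back(self):
        rng = np.random.default_rng(0)
        ct = rng.uniform(-200, 400, size=(6, 6, 6))
        w = WindowSpec()
        once = imaging.window_ct(ct, w)
        again = imaging.window_ct(once * w.width + w.low, w)
        np.testing.assert_allclose(once, again)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(70, 0)


class TestClipScalePet:
    def test_reference_points(self):
        vol = np.array([[[25.0, 50.0, 12.5, 0.0]]])
        out = imaging.clip_scale_pet(vol, 25.0)
        np.testing.assert_allclose(out, [[[1.0, 1.0, 0.5, 0.0]]])

    def test_monotone(self, rng):
        v1 = rng.uniform(0, 40, size=100)
        v2 = v1 + rng.uniform(0, 5, size=100)
        o1 = imaging.clip_scale_pet(v1)
        o2 = imaging.clip_scale_pet(v2)
        assert np.all(o1 <= o2 + 1e-12)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            imaging.clip_scale_pet(np.zeros((2, 2, 2)), 0.0)


class TestDeriveSuvCutoff:
    def test_linear_interpolation_percentile(self):
        values = np.arange(1.0, 21.0)
        expected = np.percentile(values, 95)
        assert imaging.derive_suv_cutoff(values) == pytest.approx(expected)

    def test_identical_values(self):
        assert imaging.derive_suv_cutoff([12.0] * 10) == 12.0

    def test_cutoff_not_above_cohort_max(self, rng):
        values = rng.uniform(5, 30, size=50)
        assert imaging.derive_suv_cutoff(values) <= values.max()

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            imaging.derive_suv_cutoff([10.0])


class TestCropVoi:
    def _volumes(self, shape, mask_center, mask_r=3):
        pet = np.random.default_rng(0).uniform(0, 10, size=shape)
        gtvp = np.zeros(shape, dtype=np.uint8)
        sl = tuple(slice(c - mask_r, c + mask_r) for c in mask_center)
        gtvp[sl] = 1
        return pet, gtvp

    def test_identity_when_voi_equals_grid(self):
        pet, gtvp = self._volumes((20, 20, 20), (10, 10, 10))
        out = imaging.crop_voi({"pet": pet, "gtvp": gtvp}, gtvp,
                               voi_mm=(20, 20, 20))
        np.testing.assert_array_equal(out["pet"], pet)

    def test_default_voi_shape_on_large_grid(self):
        shape = (300, 300, 300)
        gtvp = np.zeros(shape, dtype=np.uint8)
        gtvp[140:160, 140:160, 140:160] = 1
        out = imaging.crop_voi({"gtvp": gtvp}, gtvp)
        assert out["gtvp"].shape == (191, 265, 173)

    def test_gtvp_centroid_stays_inside(self):
        pet, gtvp = self._volumes((60, 60, 60), (15, 45, 30))
        out = imaging.crop_voi({"pet": pet, "gtvp": gtvp}, gtvp,
                               voi_mm=(30, 30, 30))
        assert out["gtvp"].any()
        assert out["pet"].shape == (30, 30, 30)

    def test_zero_padding_when_voi_exceeds_grid(self):
        pet, gtvp = self._volumes((20, 20, 20), (10, 10, 10))
        out = imaging.crop_voi({"pet": pet, "gtvp": gtvp}, gtvp,
                               voi_mm=(30, 20, 20))
        assert out["pet"].shape == (30, 20, 20)
        assert np.all(out["pet"][:5] == 0)

    def test_empty_mask_rejected(self):
        pet = np.zeros((10, 10, 10))
        with pytest.raises(ValueError, match="empty"):
            imaging.crop_voi({"pet": pet}, np.zeros((10, 10, 10)))


class TestSuvPeak:
    def test_uniform_region_returns_value(self):
        pet = np.full((40, 40, 40), 10.0)
        gtvp = np.zeros_like(pet, dtype=np.uint8)
        gtvp[10:30, 10:30, 10:30] = 1
        assert imaging.suv_peak(pet, gtvp) == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_phantoms(self, seed):
        rng = np.random.default_rng(seed)
        pet = rng.uniform(0, 20, size=(24, 24, 24))
        gtvp = np.zeros((24, 24, 24), dtype=np.uint8)
        center = rng.integers(8, 16, size=3)
        sl = tuple(slice(c - 3, c + 3) for c in center)
        gtvp[sl] = 1
        fast = imaging.suv_peak(pet, gtvp)
        slow = brute_force_suv_peak(pet, gtvp)
        assert fast == pytest.approx(slow, rel=1e-9)

    def test_single_voxel_mask(self):
        rng = np.random.default_rng(2)
        pet = rng.uniform(0, 5, size=(20, 20, 20))
        gtvp = np.zeros_like(pet, dtype=np.uint8)
        gtvp[10, 10, 10] = 1
        assert imaging.suv_peak(pet, gtvp) == pytest.approx(
            brute_force_suv_peak(pet, gtvp), rel=1e-9)

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(3)
        pet = rng.uniform(0, 15, size=(20, 20, 20))
        gtvp = (rng.random((20, 20, 20)) < 0.1).astype(np.uint8)
        gtvp[10, 10, 10] = 1
        base = imaging.suv_peak(pet, gtvp)
        for perm in itertools.permutations(range(3)):
            assert imaging.suv_peak(pet.transpose(perm),
                                    gtvp.transpose(perm)) == pytest.approx(base)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            imaging.suv_peak(np.zeros((5, 5, 5)), np.zeros((5, 5, 5)))


class TestMtvTlg:
    def test_uniform_uptake_counts_all_voxels(self):
        pet = np.full((20, 20, 20), 10.0)
        gtvp = np.zeros_like(pet, dtype=np.uint8)
        gtvp.ravel()[:5000] = 1
        assert imaging.mtv(pet, gtvp, 10.0) == pytest.approx(5.0)

    def test_half_below_threshold_excluded(self):
        pet = np.zeros((10, 10, 10))
        gtvp = np.zeros_like(pet, dtype=np.uint8)
        gtvp[:, :, :] = 1
        pet[:5] = 10.0
        pet[5:] = 2.0
        assert imaging.mtv(pet, gtvp, 10.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_voxel_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pet = rng.uniform(0, 20, size=(15, 15, 15))
        gtvp = (rng.random((15, 15, 15)) < 0.3).astype(np.uint8)
        gtvp[7, 7, 7] = 1
        peak = imaging.suv_peak(pet, gtvp)
        manual = sum(1 for idx in np.ndindex(pet.shape)
                     if gtvp[idx] and pet[idx] >= 0.5 * peak) / 1000.0
        assert imaging.mtv(pet, gtvp, peak) == pytest.approx(manual)

    def test_tlg_product_and_zero(self):
        assert imaging.tlg(5.0, 10.0) == 50.0
        assert imaging.tlg(0.0, 10.0) == 0.0

    def test_uniform_phantom_tlg_is_volume_times_suv(self):
        pet = np.full((20, 20, 20), 4.0)
        gtvp = np.ones_like(pet, dtype=np.uint8)
        params = imaging.pet_params(pet, gtvp)
        assert params.tlg == pytest.approx(8.0 * 4.0)  # 8 cm^3 x SUV 4

    def test_pet_params_invariants(self, small_cohort):
        _, records, _ = small_cohort
        for rec in records:
            p = imaging.pet_params(rec.pet, rec.gtvp_mask, rec.spacing)
            assert p.suv_mean <= p.suv_peak <= p.suv_max + 1e-12
            assert 0 <= p.mtv <= rec.gtvp_mask.sum() / 1000.0 + 1e-12
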