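"""NIfTI round-trips, normalization, CT resampling, slab handling."""

import numpy as np
import pytest

import nibabel as nib

from petrestore import (CTVolume, NormalizationConstants, PETVolume,
                        extract_slabs, fit_normalization, normalize,
                        denormalize, read_volume, reassemble,
                        resample_to_pet_grid, write_volume)
from petrestore.volio import FormatError, load_normalization, save_normalization


class TestNiftiIO:
    def test_round_trip(self, tmp_path, rng):
        vol = PETVolume(rng.random((10, 12, 6)), (2.34, 2.34, 2.89))
        path = tmp_path / "vol.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.data, vol.data, rtol=1e-6)
        assert back.voxel_size_mm == pytest.approx((2.34, 2.34, 2.89))

    def test_4d_payload_rejected(self, tmp_path, rng):
        img = nib.Nifti1Image(rng.random((4, 4, 4, 2)).astype(np.float32),
                              np.eye(4))
        nib.save(img, str(tmp_path / "bad.nii.gz"))
        with pytest.raises(FormatError):
            read_volume(tmp_path / "bad.nii.gz")

    def test_ct_kind(self, tmp_path, rng):
        write_volume(CTVolume(rng.random((5, 5, 5))), tmp_path / "ct.nii")
        assert isinstance(read_volume(tmp_path / "ct.nii", kind="ct"), CTVolume)

    def test_mask_round_trips_as_integers(self, tmp_path, rng):
        from petrestore.volio import write_mask
        mask = rng.random((6, 6, 3)) > 0.5
        write_mask(mask, (2.34, 2.34, 2.89), tmp_path / "mask.nii.gz")
        back = nib.load(str(tmp_path / "mask.nii.gz"))
        data = np.asanyarray(back.dataobj)
        assert data.dtype == np.uint8
        np.testing.assert_array_equal(data.astype(bool), mask)


class TestNormalization:
    def test_dataset_max_maps_to_one(self):
        vols = [PETVolume(np.full((4, 4, 4), 10.0)),
                PETVolume(np.full((4, 4, 4), 20.0))]
        consts = fit_normalization(vols)
        assert consts.pet_max_suv == 20.0
        normed = normalize(vols[1], consts)
        assert normed.data.max() == pytest.approx(1.0)

    def test_denormalize_inverts(self, rng):
        vol = PETVolume(rng.random((6, 6, 6)) * 15)
        consts = NormalizationConstants(pet_max_suv=20.0, ct_max_hu=1000.0)
        np.testing.assert_allclose(
            denormalize(normalize(vol, consts), consts).data, vol.data)

    def test_values_above_training_max_not_clipped(self):
        consts = NormalizationConstants(pet_max_suv=10.0, ct_max_hu=1000.0)
        vol = normalize(PETVolume(np.full((2, 2, 2), 30.0)), consts)
        assert vol.data.max() == pytest.approx(3.0)

    def test_all_zero_collection_rejected(self):
        with pytest.raises(ValueError):
            fit_normalization([PETVolume(np.zeros((3, 3, 3)))])

    def test_sidecar_round_trip(self, tmp_path):
        consts = NormalizationConstants(pet_max_suv=17.5, ct_max_hu=1800.0)
        for name in ("norm.yaml", "norm.json"):
            save_normalization(consts, tmp_path / name)
            assert load_normalization(tmp_path / name) == consts


class TestResample:
    def test_identity_resample(self, rng):
        ct = CTVolume(rng.random((8, 8, 8)), (2.0, 2.0, 2.0))
        pet = PETVolume(np.zeros((8, 8, 8)), (2.0, 2.0, 2.0))
        out = resample_to_pet_grid(ct, pet)
        np.testing.assert_allclose(out.data, ct.data, atol=1e-12)

    def test_constant_ct_stays_constant(self):
        ct = CTVolume(np.full((16, 16, 16), -1000.0), (1.0, 1.0, 1.0))
        pet = PETVolume(np.zeros((8, 8, 8)), (2.0, 2.0, 2.0))
        out = resample_to_pet_grid(ct, pet)
        assert out.data.shape == (8, 8, 8)
        np.testing.assert_allclose(out.data, -1000.0)

    def test_downsampling_ramp_hits_midpoints(self):
        # CT ramp along axis 0 at 1 mm; PET at 2 mm samples the midpoints
        n = 16
        ramp = np.tile(np.arange(n, dtype=float)[:, None, None], (1, n, n))
        ct = CTVolume(ramp, (1.0, 1.0, 1.0))
        pet = PETVolume(np.zeros((n // 2, n // 2, n // 2)), (2.0, 2.0, 2.0))
        out = resample_to_pet_grid(ct, pet)
        # closed-form oracle: pet center i sits at ct index 2i + 0.5
        interior = np.arange(n // 2)
        expected = 2.0 * interior + 0.5
        np.testing.assert_allclose(out.data[:, 4, 4], expected)

    def test_bad_spacing_rejected(self):
        ct = CTVolume(np.zeros((4, 4, 4)), (0.0, 1.0, 1.0))
        pet = PETVolume(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            resample_to_pet_grid(ct, pet)


class TestSlabs:
    def test_even_tiling(self, rng):
        stack = extract_slabs(rng.random((4, 4, 10)), S=5, stride=5)
        assert stack.origin_indices == [0, 5]

    def test_flush_end_rule(self, rng):
        stack = extract_slabs(rng.random((4, 4, 7)), S=5, stride=5)
        assert stack.origin_indices == [0, 2]

    @pytest.mark.parametrize("depth", [5, 6, 7, 10, 13])
    @pytest.mark.parametrize("stride", [1, 2, 5])
    def test_reassemble_inverts_extraction(self, rng, depth, stride):
        vol = rng.random((6, 6, depth))
        stack = extract_slabs(vol, S=5, stride=stride)
        np.testing.assert_allclose(reassemble(stack), vol, atol=1e-12)
        assert all(s.shape[2] == 5 for s in stack.slabs)

    def test_shallow_volume_padded_and_cropped(self, rng):
        vol = rng.random((4, 4, 3))
        stack = extract_slabs(vol, S=5)
        assert stack.pad_front == 2
        np.testing.assert_allclose(reassemble(stack), vol)

    def test_invalid_s_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_slabs(rng.random((4, 4, 8)), S=0)
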