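import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import noduleomics as no
from noduleomics.volumes import (EmptyRoiError, GeometryError, LoadError,
                                 ParameterError, quantize_array)
from conftest import make_patch
from oracles import quantize_codes


class TestReadWrite:
    def test_round_trip_is_voxel_identical(self, tmp_path, rng):
        vol = no.ImageVolume(rng.normal(size=(7, 6, 5)), (1.0, 1.5, 2.0))
        no.write_volume(vol, tmp_path / "v.nii.gz")
        back = no.read_volume(tmp_path / "v.nii.gz")
        np.testing.assert_array_equal(back.voxels, vol.voxels)
        assert back.spacing == pytest.approx(vol.spacing)

    def test_header_spacing_passthrough(self, tmp_path):
        vol = no.ImageVolume(np.zeros((10, 10, 10)), (5.0, 5.0, 5.0))
        no.write_volume(vol, tmp_path / "v.nii")
        assert no.read_volume(tmp_path / "v.nii").spacing == (5.0, 5.0, 5.0)

    def test_nan_voxels_rejected_on_load(self, tmp_path):
        import nibabel as nib

        data = np.zeros((4, 4, 4))
        data[1, 2, 3] = np.nan
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "bad.nii"))
        with pytest.raises(LoadError):
            no.read_volume(tmp_path / "bad.nii")

    def test_non_3d_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((4, 4)), np.eye(4)), str(tmp_path / "flat.nii"))
        with pytest.raises(GeometryError):
            no.read_volume(tmp_path / "flat.nii")

    def test_missing_file_names_path(self):
        with pytest.raises(LoadError, match="nowhere.nii"):
            no.read_volume("nowhere.nii")

    def test_nrrd_round_trip(self, tmp_path, rng):
        import SimpleITK as sitk

        arr = rng.normal(size=(4, 5, 6))
        img = sitk.GetImageFromArray(arr.transpose(2, 1, 0))
        img.SetSpacing((1.0, 2.0, 3.0))
        sitk.WriteImage(img, str(tmp_path / "v.nrrd"))
        back = no.read_volume(tmp_path / "v.nrrd")
        np.testing.assert_allclose(back.voxels, arr)
        assert back.spacing == (1.0, 2.0, 3.0)


class TestExtractRoi:
    def test_full_mask_is_identity(self, rng):
        vol = no.ImageVolume(rng.normal(size=(4, 5, 6)), (1, 1, 1))
        patch = no.extract_roi(vol, np.ones((4, 5, 6), bool))
        np.testing.assert_array_equal(patch.voxels, vol.voxels)
        assert patch.n_voxels == 4 * 5 * 6

    def test_single_voxel(self, rng):
        vol = no.ImageVolume(rng.normal(size=(8, 8, 8)), (1, 1, 1))
        mask = np.zeros((8, 8, 8), bool)
        mask[3, 4, 5] = True
        patch = no.extract_roi(vol, mask)
        assert patch.shape == (1, 1, 1)
        assert patch.n_voxels == 1
        assert patch.voxels[0, 0, 0] == vol.voxels[3, 4, 5]

    def test_bounds_match_brute_force_index_scan(self, rng):
        vol = no.ImageVolume(rng.normal(size=(20, 20, 20)), (1, 1, 1))
        mask = rng.random((20, 20, 20)) < 0.05
        mask[2, 3, 4] = True  # guarantee non-empty
        patch = no.extract_roi(vol, mask)
        idx = np.argwhere(mask)
        lo, hi = idx.min(axis=0), idx.max(axis=0)
        expected_shape = tuple(hi - lo + 1)
        assert patch.shape == expected_shape
        np.testing.assert_array_equal(
            patch.voxels, vol.voxels[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        )
        assert patch.n_voxels == mask.sum()

    def test_empty_mask_raises(self):
        vol = no.ImageVolume(np.zeros((3, 3, 3)), (1, 1, 1))
        with pytest.raises(EmptyRoiError, match="empty ROI"):
            no.extract_roi(vol, np.zeros((3, 3, 3), bool))

    def test_shape_mismatch_raises(self):
        vol = no.ImageVolume(np.zeros((3, 3, 3)), (1, 1, 1))
        with pytest.raises(GeometryError):
            no.extract_roi(vol, np.ones((4, 3, 3), bool))

    def test_crop_commutes_with_padding(self, random_patch):
        """Padding with out-of-mask voxels then re-cropping is a no-op."""
        vox = np.pad(random_patch.voxels, 2, constant_values=999.0)
        msk = np.pad(random_patch.mask, 2, constant_values=False)
        vol = no.ImageVolume(vox, random_patch.spacing)
        again = no.extract_roi(vol, msk)
        np.testing.assert_array_equal(again.mask, random_patch.mask)
        np.testing.assert_array_equal(again.voxels[again.mask],
                                      random_patch.voxels[random_patch.mask])


class TestQuantize:
    def test_constant_patch_maps_to_code_zero(self):
        q = no.quantize(make_patch(np.full((3, 3, 3), 7.0)), 256)
        assert set(q.codes.ravel()) == {0}

    def test_extremes_hit_first_and_last_bin(self):
        vox = np.array([0.0, 255.0]).reshape(2, 1, 1)
        q = no.quantize(make_patch(vox), 256)
        assert sorted(q.codes.ravel()) == [0, 255]

    def test_levels_below_two_rejected(self):
        with pytest.raises(ParameterError):
            no.quantize(make_patch(np.zeros((2, 2, 2))), 1)

    def test_sentinel_outside_mask(self, random_patch):
        q = no.quantize(random_patch, 16)
        assert (q.codes[~random_patch.mask] == -1).all()
        assert (q.codes[random_patch.mask] >= 0).all()

    @settings(derandomize=True, max_examples=50)
    @given(
        vals=st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=1, max_size=30),
        levels=st.integers(2, 64),
    )
    def test_codes_match_floor_division_oracle(self, vals, levels):
        vox = np.array(vals).reshape(-1, 1, 1)
        mask = np.ones(vox.shape, bool)
        codes = quantize_array(vox, mask, levels)
        np.testing.assert_array_equal(codes, quantize_codes(vox, levels))
        # order preserving
        flat_v = vox.ravel()
        flat_c = codes.ravel()
        order = np.argsort(flat_v, kind="stable")
        assert (np.diff(flat_c[order]) >= 0).all()

    def test_idempotent_at_code_level(self, rng):
        vox = rng.integers(0, 64, size=(6, 6, 6)).astype(float)
        mask = np.ones(vox.shape, bool)
        c1 = quantize_array(vox, mask, 64)
        c2 = quantize_array(c1.astype(float), mask, 64)
        np.testing.assert_array_equal(c1, c2)


def test_manifest_round_trip(tmp_path):
    import pandas as pd

    frame = pd.DataFrame(
        {"case_id": ["a", "b"], "image_path": ["a.nii", "b.nii"],
         "mask_path": ["am.nii", "bm.nii"], "label": ["benign", "malignant"]}
    )
    frame.to_csv(tmp_path / "m.csv", index=False)
    back = no.read_manifest(tmp_path / "m.csv")
    assert list(back["case_id"]) == ["a", "b"]
    assert back["image_path"][0] == str(tmp_path / "a.nii")
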