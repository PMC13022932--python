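"""Preprocessing chain: orientation, resampling, windowing, normalisation."""

import numpy as np
import nibabel as nib
import pytest

from fedbids.preprocess import (
    PipelineError,
    PreprocessConfig,
    crop_or_pad,
    normalize_intensity,
    preprocess_pipeline,
    resample_isotropic,
    to_ras,
)

RNG = np.random.default_rng(7)


def test_to_ras_is_identity_on_ras_input():
    vol = RNG.random((6, 7, 8)).astype(np.float32)
    out, aff = to_ras(vol, np.eye(4))
    np.testing.assert_array_equal(out, vol)
    np.testing.assert_allclose(aff, np.eye(4))


def test_to_ras_flips_lps_and_is_idempotent():
    vol = RNG.random((6, 7, 8)).astype(np.float32)
    lps = np.diag([-1.0, -1.0, 1.0, 1.0])  # L and P point the wrong way
    out, aff = to_ras(vol, lps)
    np.testing.assert_array_equal(out, vol[::-1, ::-1, :])
    out2, aff2 = to_ras(out, aff)
    np.testing.assert_array_equal(out2, out)
    np.testing.assert_allclose(aff2, aff)


def test_to_ras_preserves_world_coordinates():
    vol = RNG.random((5, 6, 7)).astype(np.float32)
    affine = np.array([[0, 0, 1.2, 3.0],
                       [-1.1, 0, 0, -2.0],
                       [0, 0.9, 0, 5.0],
                       [0, 0, 0, 1.0]])
    out, new_affine = to_ras(vol, affine)
    rng = np.random.default_rng(1)
    for _ in range(10):
        idx = tuple(rng.integers(0, s) for s in vol.shape)
        world = affine @ np.array([*idx, 1.0])
        # locate the same voxel value's new index by inverting the mapping
        new_idx = np.linalg.solve(new_affine, world)[:3]
        new_idx = tuple(int(round(v)) for v in new_idx)
        assert out[new_idx] == vol[idx]


def test_to_ras_rejects_singular_affine():
    with pytest.raises(ValueError, match="singular"):
        to_ras(np.zeros((4, 4, 4)), np.zeros((4, 4)))


def test_resample_140_at_1mm_gives_100_at_1p4():
    vol = RNG.random((140, 140, 140)).astype(np.float32)
    out, aff = resample_isotropic(vol, np.eye(4), target_spacing=1.4)
    assert out.shape == (100, 100, 100)
    np.testing.assert_allclose(np.sqrt((aff[:3, :3] ** 2).sum(axis=0)), 1.4)


def test_resample_identity_when_already_at_target():
    vol = RNG.random((20, 24, 28)).astype(np.float32)
    aff = np.diag([1.4, 1.4, 1.4, 1.0])
    out, _ = resample_isotropic(vol, aff, target_spacing=1.4)
    assert out.shape == vol.shape
    np.testing.assert_allclose(out, vol, atol=1e-6)


def test_resample_preserves_constants():
    vol = np.full((30, 30, 30), 3.25, dtype=np.float32)
    out, _ = resample_isotropic(vol, np.eye(4), target_spacing=1.4)
    np.testing.assert_allclose(out, 3.25, atol=1e-6)


def test_crop_retains_central_block():
    vol = RNG.random((160, 160, 160)).astype(np.float32)
    out = crop_or_pad(vol, 130)
    assert out.shape == (130, 130, 130)
    np.testing.assert_array_equal(out, vol[15:145, 15:145, 15:145])


def test_pad_adds_symmetric_zero_margins():
    vol = RNG.random((100, 100, 100)).astype(np.float32)
    out = crop_or_pad(vol, 130)
    assert out.shape == (130, 130, 130)
    np.testing.assert_array_equal(out[15:115, 15:115, 15:115], vol)
    assert out[:15].sum() == 0 and out[115:].sum() == 0


def test_crop_pad_identity_and_idempotence():
    vol = RNG.random((130, 130, 130)).astype(np.float32)
    np.testing.assert_array_equal(crop_or_pad(vol, 130), vol)
    odd = RNG.random((133, 127, 130)).astype(np.float32)
    once = crop_or_pad(odd, 130)
    assert once.shape == (130, 130, 130)
    np.testing.assert_array_equal(crop_or_pad(once, 130), once)
    # odd remainders go to the trailing side: crop 133 → keep [1, 131);
    # pad 127 → 1 leading zero plane, 2 trailing zero planes
    np.testing.assert_array_equal(once[:, 1:128, :], odd[1:131, :, :])
    assert once[:, 0, :].sum() == 0
    assert once[:, 128:, :].sum() == 0


def test_normalize_modes():
    vol = RNG.random((10, 10, 10)).astype(np.float32) * 7 + 3
    mm = normalize_intensity(vol, "minmax")
    assert mm.min() == pytest.approx(0.0) and mm.max() == pytest.approx(1.0)
    zs = normalize_intensity(vol, "zscore")
    assert abs(zs.mean()) < 1e-5 and abs(zs.std() - 1) < 1e-5
    np.testing.assert_array_equal(normalize_intensity(vol, "none"), vol)
    with pytest.raises(ValueError, match="constant"):
        normalize_intensity(np.ones((4, 4, 4)), "minmax")


def _write_phantom(tmp_path, shape=(64, 72, 60), spacing=1.0):
    vol = RNG.random(shape).astype(np.float32)
    path = tmp_path / "input.nii.gz"
    nib.save(nib.Nifti1Image(vol, np.diag([spacing] * 3 + [1.0])), str(path))
    return path


def test_pipeline_output_shape_contract(tmp_path):
    path = _write_phantom(tmp_path, shape=(64, 72, 60))
    out = preprocess_pipeline(path, PreprocessConfig(window=50))
    assert out.shape == (1, 50, 50, 50)
    assert out.dtype == np.float32


def test_pipeline_cache_returns_identical_array(tmp_path):
    path = _write_phantom(tmp_path)
    cfg = PreprocessConfig(window=40)
    cache = tmp_path / "cache"
    first = preprocess_pipeline(path, cfg, cache_dir=cache)
    assert len(list(cache.glob("*.npy"))) == 1
    second = preprocess_pipeline(path, cfg, cache_dir=cache)
    np.testing.assert_array_equal(first, second)


def test_pipeline_identity_hook_runs(tmp_path):
    path = _write_phantom(tmp_path)
    cfg = PreprocessConfig(window=40,
                           external_hooks={"skull_strip": "cp {in} {out}"})
    plain = preprocess_pipeline(path, PreprocessConfig(window=40))
    hooked = preprocess_pipeline(path, cfg)
    np.testing.assert_allclose(hooked, plain, atol=1e-5)


def test_pipeline_failing_hook_is_named(tmp_path):
    path = _write_phantom(tmp_path)
    cfg = PreprocessConfig(
        external_hooks={"bias_correct": "/no/such/tool {in} {out}"})
    with pytest.raises(PipelineError, match="bias_correct"):
        preprocess_pipeline(path, cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(target_spacing=-1)
    with pytest.raises(ValueError):
        PreprocessConfig(normalize="log")
    with pytest.raises(ValueError):
        PreprocessConfig(external_hooks={"defacing": "x"})
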