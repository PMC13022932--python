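"""Deterministic NIfTI standardisation for model input.

Implements the tail of the Wood-style brain-age preparation chain that can
run without third-party binaries: RAS reorientation, isotropic resampling
(default 1.4 mm), centre crop / symmetric zero-pad to a cubic window
(default 130³) and per-volume intensity normalisation.  Skull stripping,
bias-field correction and affine template registration are external tools in
that chain, so here they are pluggable command hooks operating on temporary
NIfTI files — configured, they run; unconfigured, they are skipped.
"""

from __future__ import annotations

import hashlib
import json
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .bids_io import load_volume

__all__ = [
    "PreprocessConfig", "PipelineError", "to_ras", "resample_isotropic",
    "crop_or_pad", "normalize_intensity", "preprocess_pipeline",
]

HOOK_ORDER = ("skull_strip", "bias_correct", "affine_register")


class PipelineError(RuntimeError):
    """An external hook or pipeline stage failed."""


@dataclass(frozen=True)
class PreprocessConfig:
    target_spacing: float = 1.4
    window: int = 130
    interpolation: str = "linear"
    normalize: str = "minmax"
    external_hooks: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.target_spacing <= 0 or self.window <= 0:
            raise ValueError("target_spacing and window must be positive")
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError("interpolation must be 'linear' or 'nearest'")
        if self.normalize not in ("minmax", "zscore", "none"):
            raise ValueError("normalize must be 'minmax', 'zscore' or 'none'")
        unknown = set(self.external_hooks) - set(HOOK_ORDER)
        if unknown:
            raise ValueError(f"unknown hooks: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {"target_spacing": self.target_spacing, "window": self.window,
                "interpolation": self.interpolation,
                "normalize": self.normalize,
                "external_hooks": dict(self.external_hooks)}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**d)


def to_ras(volume: np.ndarray,
           affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reorder/flip axes so voxel indices increase towards R, A, S.

    Pure axis permutation and flipping — no resampling — with the affine
    updated so every voxel keeps its world coordinate.  Idempotent.
    """
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular; orientation is undefined")
    current = nib.orientations.io_orientation(affine)
    target = nib.orientations.axcodes2ornt(("R", "A", "S"))
    transform = nib.orientations.ornt_transform(current, target)
    out = nib.orientations.apply_orientation(volume, transform)
    new_affine = affine @ nib.orientations.inv_ornt_aff(transform,
                                                        volume.shape)
    return np.ascontiguousarray(out), new_affine


def resample_isotropic(volume: np.ndarray, affine: np.ndarray,
                       target_spacing: float = 1.4,
                       interpolation: str = "linear"
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Resample to isotropic voxels; output shape = round(extent / spacing)."""
    affine = np.asarray(affine, dtype=float)
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if np.any(spacing <= 0):
        raise ValueError("affine encodes non-positive voxel spacing")
    in_shape = np.array(volume.shape)
    out_shape = np.maximum(
        np.round(in_shape * spacing / target_spacing).astype(int), 1)
    scale = target_spacing / spacing  # input voxels per output voxel
    coords = np.meshgrid(*(np.arange(n) * s for n, s in zip(out_shape, scale)),
                         indexing="ij")
    order = 1 if interpolation == "linear" else 0
    out = map_coordinates(volume.astype(np.float32), coords, order=order,
                          mode="nearest")
    new_affine = affine.copy()
    new_affine[:3, :3] = affine[:3, :3] * scale[np.newaxis, :]
    return out.astype(np.float32), new_affine


def crop_or_pad(volume: np.ndarray, window: int) -> np.ndarray:
    """Centre-crop / symmetric zero-pad each axis to ``window`` voxels.

    The odd voxel of an odd size difference is taken from / added to the
    trailing side of the axis.
    """
    out = volume
    for axis in range(3):
        n = out.shape[axis]
        if n > window:
            start = (n - window) // 2
            sl = [slice(None)] * 3
            sl[axis] = slice(start, start + window)
            out = out[tuple(sl)]
        elif n < window:
            before = (window - n) // 2
            after = window - n - before
            pad = [(0, 0)] * 3
            pad[axis] = (before, after)
            out = np.pad(out, pad)
    return np.ascontiguousarray(out)


def normalize_intensity(volume: np.ndarray, mode: str = "minmax") -> np.ndarray:
    if mode == "none":
        return volume
    lo, hi = float(volume.min()), float(volume.max())
    if hi == lo:
        raise ValueError(f"constant-valued volume cannot be {mode}-normalised")
    if mode == "minmax":
        return ((volume - lo) / (hi - lo)).astype(np.float32)
    if mode == "zscore":
        return ((volume - volume.mean()) / volume.std()).astype(np.float32)
    raise ValueError(f"unknown normalisation mode {mode!r}")


def _run_hook(name: str, template: str, volume: np.ndarray,
              affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with tempfile.TemporaryDirectory(prefix=f"fedbids_{name}_") as tmp:
        fin = Path(tmp) / "in.nii.gz"
        fout = Path(tmp) / "out.nii.gz"
        nib.save(nib.Nifti1Image(volume.astype(np.float32), affine), str(fin))
        cmd = template.format(**{"in": str(fin), "out": str(fout)})
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0 or not fout.exists():
            raise PipelineError(
                f"hook '{name}' failed (exit {proc.returncode}): "
                f"{proc.stderr.strip() or cmd}")
        vd = load_volume(fout)
        return vd.data, vd.affine


def _cache_key(path: Path, config: PreprocessConfig) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    h.update(json.dumps(config.to_dict(), sort_keys=True).encode())
    return h.hexdigest()


def preprocess_pipeline(path: str | Path, config: PreprocessConfig,
                        cache_dir: str | Path | None = None) -> np.ndarray:
    """Full standardisation of one NIfTI file → (1, window³) float32 array.

    Stage order: RAS → [skull_strip] → [bias_correct] → [affine_register] →
    RAS → isotropic resample → crop/pad → intensity normalisation.  Results
    are cached under ``cache_dir`` keyed by the input bytes and the config.
    """
    path = Path(path)
    cache_file = None
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache_file = cache_dir / (_cache_key(path, config) + ".npy")
        if cache_file.exists():
            return np.load(cache_file)
    vd = load_volume(path)
    vol, affine = to_ras(vd.data, vd.affine)
    for name in HOOK_ORDER:
        template = config.external_hooks.get(name)
        if template:
            vol, affine = _run_hook(name, template, vol, affine)
    vol, affine = to_ras(vol, affine)
    vol, affine = resample_isotropic(vol, affine, config.target_spacing,
                                     config.interpolation)
    vol = crop_or_pad(vol, config.window)
    vol = normalize_intensity(vol, config.normalize)
    out = vol[np.newaxis].astype(np.float32)
    if cache_file is not None:
        np.save(cache_file, out)
    return out
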